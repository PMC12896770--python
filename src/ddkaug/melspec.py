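"""Log-Mel spectrogram frontend.

Each 2560-sample (160 ms, 16 kHz) segment becomes an 80-band x 41-frame
dB matrix: STFT with a 256-sample Hann window and hop 64, centered
(reflect-padded) framing — which yields exactly 1 + floor(2560/64) = 41
frames — power spectra projected onto an 80-band Slaney-style mel
filterbank spanning 0–8000 Hz, then 10*log10 relative to the per-segment
maximum with a floor at -80 dB.  The representation is therefore scale
invariant: multiplying a segment by any positive constant leaves the
matrix unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import get_window

from .errors import ShapeError
from .preprocess import SEGMENT_LEN, Segment

N_FFT = 256
HOP = 64
N_MELS = 80
FMIN = 0.0
FMAX = 8000.0
SR = 16000
N_FRAMES = 1 + SEGMENT_LEN // HOP   # 41, centered framing
DB_FLOOR = -80.0

# Slaney mel scale: linear below 1 kHz, logarithmic above
_F_SP = 200.0 / 3
_MIN_LOG_HZ = 1000.0
_MIN_LOG_MEL = _MIN_LOG_HZ / _F_SP
_LOGSTEP = np.log(6.4) / 27.0


def hz_to_mel(f):
    f = np.asanyarray(f, dtype=np.float64)
    mel = f / _F_SP
    log_region = f >= _MIN_LOG_HZ
    mel = np.where(log_region,
                   _MIN_LOG_MEL + np.log(np.maximum(f, _MIN_LOG_HZ) / _MIN_LOG_HZ) / _LOGSTEP,
                   mel)
    return mel


def mel_to_hz(m):
    m = np.asanyarray(m, dtype=np.float64)
    f = m * _F_SP
    log_region = m >= _MIN_LOG_MEL
    f = np.where(log_region, _MIN_LOG_HZ * np.exp(_LOGSTEP * (m - _MIN_LOG_MEL)), f)
    return f


@lru_cache(maxsize=4)
def mel_filterbank(n_mels: int = N_MELS, n_fft: int = N_FFT, sr: int = SR,
                   fmin: float = FMIN, fmax: float = FMAX) -> np.ndarray:
    """Triangular Slaney-normalized filterbank, shape (n_mels, n_fft//2 + 1).

    With 129 FFT bins and 80 bands some low-frequency triangles can miss
    every bin center; such rows are all-zero and simply produce floor
    values downstream.
    """
    fft_freqs = np.linspace(0, sr / 2, n_fft // 2 + 1)
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lower, center, upper = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lower) / max(center - lower, 1e-12)
        down = (upper - fft_freqs) / max(upper - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (upper - lower)   # Slaney area normalization
    return fb


def mel_center_freqs(n_mels: int = N_MELS, fmin: float = FMIN,
                     fmax: float = FMAX) -> np.ndarray:
    """Center frequency (Hz) of each mel band."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(mel_pts)[1:-1]


@dataclass
class MelSpectrogram:
    """An 80x41 dB matrix with provenance back to its segment."""

    values: np.ndarray            # (N_MELS, N_FRAMES), dB, <= 0, >= DB_FLOOR
    segment_id: str
    subject_id: str
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_MELS, N_FRAMES):
            raise ShapeError(
                f"mel matrix must be {N_MELS}x{N_FRAMES}, got {self.values.shape}")


def _stft_power(x: np.ndarray) -> np.ndarray:
    """Centered power STFT, shape (n_fft//2 + 1, n_frames)."""
    pad = N_FFT // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + (len(xp) - N_FFT) // HOP
    idx = np.arange(N_FFT)[None, :] + HOP * np.arange(n_frames)[:, None]
    frames = xp[idx] * get_window("hann", N_FFT, fftbins=True)
    spec = np.fft.rfft(frames, axis=1)
    return (spec.real ** 2 + spec.imag ** 2).T


def compute_melspec(segment: Segment) -> MelSpectrogram:
    """Compute the log-mel matrix of one 160 ms segment."""
    x = segment.samples
    if x.shape != (SEGMENT_LEN,):
        raise ShapeError(f"segment must have {SEGMENT_LEN} samples, got {x.shape}")
    power = _stft_power(x)
    mel_power = mel_filterbank() @ power
    ref = mel_power.max()
    if ref <= 0:
        values = np.full((N_MELS, N_FRAMES), DB_FLOOR)
    else:
        values = 10.0 * np.log10(np.maximum(mel_power / ref, 10.0 ** (DB_FLOOR / 10)))
    seg_id = f"{segment.parent_recording}@{segment.start_sample}"
    return MelSpectrogram(values=values, segment_id=seg_id,
                          subject_id=segment.subject_id, label=segment.label)


def batch_melspec(segments: list[Segment]) -> list[MelSpectrogram]:
    """Elementwise :func:`compute_melspec`, preserving order and provenance."""
    out = []
    for i, seg in enumerate(segments):
        try:
            out.append(compute_melspec(seg))
        except Exception as exc:
            raise type(exc)(f"segment {i}: {exc}") from exc
    return out
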