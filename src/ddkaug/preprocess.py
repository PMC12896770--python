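"""Recording standardization and fixed-window segmentation.

Every recording is peak-normalized, downmixed to mono, resampled to
16 kHz, and cut into 160 ms windows (2560 samples) with 50% overlap
(hop 1280 samples).  The fixed window geometry is what guarantees the
80x41 spectrogram contract downstream, so it is not configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .errors import DegenerateInputError, ParameterError
from .synthetic import AudioRecording

logger = logging.getLogger(__name__)

TARGET_SR = 16000
SEGMENT_S = 0.160
SEGMENT_LEN = int(SEGMENT_S * TARGET_SR)   # 2560
HOP_LEN = SEGMENT_LEN // 2                 # 1280, i.e. 50% overlap


@dataclass
class Segment:
    """One 160 ms window of a standardized recording."""

    samples: np.ndarray           # exactly SEGMENT_LEN samples
    parent_recording: str         # "<subject_id>/<task_id>"
    start_sample: int             # offset in the 16 kHz parent
    subject_id: str
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (SEGMENT_LEN,):
            raise ParameterError(
                f"segment must have {SEGMENT_LEN} samples, got {self.samples.shape}")


def normalize_amplitude(recording: AudioRecording) -> AudioRecording:
    """Peak-normalize so that max |sample| = 1.

    Scaling is uniform across channels; an all-zero signal has no
    defined scale and is rejected.
    """
    peak = np.max(np.abs(recording.samples))
    if peak == 0:
        raise DegenerateInputError("cannot normalize an all-zero signal")
    return AudioRecording(samples=recording.samples / peak,
                          sample_rate=recording.sample_rate,
                          subject_id=recording.subject_id,
                          label=recording.label, task_id=recording.task_id)


def to_mono(recording: AudioRecording) -> AudioRecording:
    """Downmix to a single channel by the arithmetic mean across channels."""
    if recording.samples.ndim == 1:
        return recording
    return AudioRecording(samples=recording.samples.mean(axis=0),
                          sample_rate=recording.sample_rate,
                          subject_id=recording.subject_id,
                          label=recording.label, task_id=recording.task_id)


def resample_to_16k(recording: AudioRecording) -> AudioRecording:
    """Band-limited (polyphase) resampling to 16 kHz; identity at 16 kHz."""
    sr = recording.sample_rate
    if sr == TARGET_SR:
        return recording
    if sr < 8000:
        raise ParameterError(f"source sample rate {sr} Hz unsupported (< 8 kHz)")
    ratio = Fraction(TARGET_SR, sr)
    samples = resample_poly(recording.samples, ratio.numerator,
                            ratio.denominator, axis=-1)
    return AudioRecording(samples=samples, sample_rate=TARGET_SR,
                          subject_id=recording.subject_id,
                          label=recording.label, task_id=recording.task_id)


def segment_recording(recording: AudioRecording) -> list[Segment]:
    """Cut a standardized recording into 2560-sample windows, hop 1280.

    Windows start at 0, 1280, 2560, ...; a tail shorter than a full
    window is dropped, so a recording of n samples yields
    floor((n - 2560)/1280) + 1 segments (0 if n < 2560).
    """
    if recording.sample_rate != TARGET_SR:
        raise ParameterError(
            f"segment_recording requires {TARGET_SR} Hz input, got {recording.sample_rate}")
    if recording.samples.ndim != 1:
        raise ParameterError("segment_recording requires a mono recording")
    n = recording.n_samples
    parent = f"{recording.subject_id}/{recording.task_id}"
    if n < SEGMENT_LEN:
        logger.warning("recording %s too short to segment (%d samples)", parent, n)
        return []
    segments = []
    for start in range(0, n - SEGMENT_LEN + 1, HOP_LEN):
        segments.append(Segment(samples=recording.samples[start:start + SEGMENT_LEN],
                                parent_recording=parent, start_sample=start,
                                subject_id=recording.subject_id,
                                label=recording.label))
    return segments


def standardize(recording: AudioRecording) -> AudioRecording:
    """normalize -> mono -> resample, in that order."""
    return resample_to_16k(to_mono(normalize_amplitude(recording)))


def preprocess_recording(recording: AudioRecording) -> list[Segment]:
    """Full pipeline: standardize then segment."""
    return segment_recording(standardize(recording))
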