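"""Synthetic diadochokinetic (DDK) speech cohorts.

Real DDK corpora for Parkinson's disease research (rapid /pa-ta-ka/
repetition recorded per subject) are access-restricted, so this module
generates seeded, subject-structured stand-in cohorts: two classes (PD
patients and healthy controls, HC) whose recordings are syllable-like
pulse trains.  Each syllable is a short white-noise burst (the plosive)
followed by an exponentially decaying harmonic complex (the vowel), and
the two classes differ in syllable rate, amplitude-modulation depth,
timing regularity and background-noise level — a caricature of
hypokinetic dysarthria (slowed DDK rate, reduced intensity modulation,
breathier signal), not a phonetic model of it.

The generator is deterministic: one seed fully determines the cohort,
and each subject draws from an independent, counter-addressed random
stream, so enlarging a cohort never reshuffles existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import DataError, ParameterError

LABELS = ("HC", "PD")

# fixed acoustics of the syllable model (not class-dependent)
_BURST_S = 0.010          # plosive noise burst length
_VOWEL_S = 0.060          # harmonic complex length
_VOWEL_DECAY_S = 0.020    # amplitude e-folding time of the vowel
_N_HARMONICS = 8
_BASE_F0_HZ = 120.0
_BASE_NOISE = 0.005       # HC background-noise amplitude (linear, re peak 1)
_BASE_JITTER_S = 0.008    # HC per-syllable onset jitter SD
_PEAK = 0.9               # output peak amplitude (headroom for 16-bit I/O)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-class synthetic DDK cohort.

    Class effects are expressed as deficits subtracted from (or, for
    noise, added to) the healthy-control means; with all deficits zero
    the two classes are drawn from identical distributions.
    """

    n_subjects_per_class: int = 25
    recordings_per_subject: int = 1
    duration_s: float = 4.0
    sample_rate: int = 16000
    hc_syllable_rate: float = 5.5      # syllables/s, typical /pa-ta-ka/ pace
    pd_rate_deficit: float = 1.0       # syllables/s subtracted for PD
    hc_mod_depth: float = 0.9          # fraction of envelope swing, 0-1
    pd_mod_depth_deficit: float = 0.3
    pd_noise_excess: float = 0.02      # linear amplitude added to PD noise
    subject_sd: float = 0.08           # relative between-subject SD
    subject_prefix: str = ""           # distinguishes cohorts sharing a namespace
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ParameterError("n_subjects_per_class must be >= 1")
        if self.recordings_per_subject < 1:
            raise ParameterError("recordings_per_subject must be >= 1")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.sample_rate < 8000:
            raise ParameterError("sample_rate must be >= 8000 Hz")
        if self.hc_syllable_rate <= 0:
            raise ParameterError("hc_syllable_rate must be > 0")
        if self.pd_rate_deficit < 0 or self.pd_rate_deficit >= self.hc_syllable_rate:
            raise ParameterError(
                "pd_rate_deficit must be in [0, hc_syllable_rate)")
        if not 0.0 <= self.hc_mod_depth <= 1.0:
            raise ParameterError("hc_mod_depth must be in [0, 1]")
        if self.pd_mod_depth_deficit < 0 or self.pd_mod_depth_deficit > self.hc_mod_depth:
            raise ParameterError(
                "pd_mod_depth_deficit must be in [0, hc_mod_depth]")
        if self.pd_noise_excess < 0:
            raise ParameterError("pd_noise_excess must be >= 0")
        if self.subject_sd < 0:
            raise ParameterError("subject_sd must be >= 0")

    def null(self) -> "CohortSpec":
        """Copy of this spec with all class effects removed (PD ≡ HC)."""
        return replace(self, pd_rate_deficit=0.0, pd_mod_depth_deficit=0.0,
                       pd_noise_excess=0.0)


@dataclass
class AudioRecording:
    """A labeled, subject-tagged waveform.

    ``samples`` is 1-D (mono) or ``(n_channels, n)`` float64 in [-1, 1].
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str
    label: str
    task_id: str = "ddk"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ParameterError("samples must be 1-D or (n_channels, n)")
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]


@dataclass
class _SubjectParams:
    rate: float
    mod_depth: float
    noise: float
    jitter_s: float
    f0: float


def _subject_params(spec: CohortSpec, class_idx: int, subj_idx: int) -> _SubjectParams:
    """Draw one subject's latent traits from a counter-addressed stream."""
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, class_idx, subj_idx)))
    z = rng.standard_normal(3)
    pd = class_idx == 1
    rate_mean = spec.hc_syllable_rate - (spec.pd_rate_deficit if pd else 0.0)
    depth_mean = spec.hc_mod_depth - (spec.pd_mod_depth_deficit if pd else 0.0)
    noise = _BASE_NOISE + (spec.pd_noise_excess if pd else 0.0)
    # PD timing irregularity grows continuously with the modulation deficit,
    # so zero deficits keep the two classes identically distributed
    jitter = _BASE_JITTER_S * (1.0 + (2.0 * spec.pd_mod_depth_deficit if pd else 0.0))
    rate = max(0.5, rate_mean * (1.0 + spec.subject_sd * z[0]))
    depth = float(np.clip(depth_mean * (1.0 + spec.subject_sd * z[1]), 0.0, 1.0))
    f0 = max(60.0, _BASE_F0_HZ * (1.0 + spec.subject_sd * z[2]))
    return _SubjectParams(rate, depth, noise, jitter, f0)


def _syllable(rng: np.random.Generator, sr: int, f0: float) -> np.ndarray:
    """One syllable: 10 ms noise burst then 60 ms decaying harmonic complex."""
    n_burst = int(round(_BURST_S * sr))
    n_vowel = int(round(_VOWEL_S * sr))
    burst = 0.5 * rng.standard_normal(n_burst)
    t = np.arange(n_vowel) / sr
    decay = np.exp(-t / _VOWEL_DECAY_S)
    vowel = np.zeros(n_vowel)
    phases = rng.uniform(0, 2 * np.pi, _N_HARMONICS)
    for h in range(1, _N_HARMONICS + 1):
        vowel += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + phases[h - 1])
    vowel *= decay
    syl = np.concatenate([burst, vowel])
    peak = np.max(np.abs(syl))
    return syl / peak if peak > 0 else syl


def _synthesize(spec: CohortSpec, params: _SubjectParams,
                rng: np.random.Generator) -> np.ndarray:
    sr = spec.sample_rate
    n = int(round(spec.duration_s * sr))
    x = np.zeros(n)
    # jittered syllable onsets at the subject's rate
    k = 0
    while True:
        onset = k / params.rate + params.jitter_s * rng.standard_normal()
        if k / params.rate >= spec.duration_s:
            break
        i0 = int(round(onset * sr))
        if i0 < n:
            syl = _syllable(rng, sr, params.f0)
            i0 = max(i0, 0)
            seg = syl[: n - i0]
            x[i0:i0 + len(seg)] += seg
        k += 1
    # continuous harmonic bed: shallow modulation = loud bed (hypokinetic)
    bed_amp = 1.0 - params.mod_depth
    if bed_amp > 0:
        t = np.arange(n) / sr
        phase = rng.uniform(0, 2 * np.pi)
        x += bed_amp * np.sin(2 * np.pi * params.f0 * t + phase)
    x += params.noise * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= _PEAK / peak
    return x


def generate_cohort(spec: CohortSpec) -> list[AudioRecording]:
    """Generate the full two-class cohort described by ``spec``.

    Returns ``2 * n_subjects_per_class`` subjects' recordings in a fixed
    order (HC subjects first, then PD; within a subject, recordings in
    task order).  Identical spec and seed give bit-identical output.
    """
    cohort: list[AudioRecording] = []
    for class_idx, label in enumerate(LABELS):
        for subj_idx in range(spec.n_subjects_per_class):
            params = _subject_params(spec, class_idx, subj_idx)
            subject_id = f"{spec.subject_prefix}{label}{subj_idx:03d}"
            for rec_idx in range(spec.recordings_per_subject):
                rng = np.random.default_rng(np.random.SeedSequence(
                    (spec.seed, class_idx, subj_idx, 1 + rec_idx)))
                samples = _synthesize(spec, params, rng)
                cohort.append(AudioRecording(
                    samples=samples, sample_rate=spec.sample_rate,
                    subject_id=subject_id, label=label,
                    task_id=f"ddk{rec_idx:02d}"))
    return cohort


MANIFEST_NAME = "manifest.csv"


def write_cohort_wav(cohort: list[AudioRecording], directory: str | Path) -> Path:
    """Write a cohort as 16-bit PCM WAV files plus a CSV manifest.

    Returns the manifest path; the manifest maps each file to its
    subject_id, label and task_id.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        fname = f"{rec.subject_id}_{rec.task_id}.wav"
        data = np.clip(rec.samples, -1.0, 1.0)
        pcm = np.round(data * 32767.0).astype(np.int16)
        wavfile.write(directory / fname, rec.sample_rate, pcm.T)
        rows.append({"file": fname, "subject_id": rec.subject_id,
                     "label": rec.label, "task_id": rec.task_id})
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=["file", "subject_id", "label", "task_id"]
                 ).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> list[AudioRecording]:
    """Read a cohort back from a manifest written by :func:`write_cohort_wav`."""
    manifest = Path(manifest)
    if not manifest.exists():
        raise DataError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest)
    required = {"file", "subject_id", "label", "task_id"}
    if not required.issubset(table.columns):
        raise DataError(f"manifest missing columns {required - set(table.columns)}")
    cohort: list[AudioRecording] = []
    for row in table.itertuples(index=False):
        if row.label not in LABELS:
            raise DataError(f"unknown label {row.label!r} for {row.file}")
        path = manifest.parent / row.file
        if not path.exists():
            raise DataError(f"missing WAV file: {path}")
        sr, pcm = wavfile.read(path)
        samples = pcm.astype(np.float64).T / 32767.0
        cohort.append(AudioRecording(samples=samples, sample_rate=int(sr),
                                     subject_id=str(row.subject_id),
                                     label=str(row.label),
                                     task_id=str(row.task_id)))
    return cohort
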