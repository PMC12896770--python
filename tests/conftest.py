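import numpy as np
import pytest

from ddkaug.melspec import MelSpectrogram, N_FRAMES, N_MELS
from ddkaug.preprocess import SEGMENT_LEN, Segment
from ddkaug.synthetic import AudioRecording, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 subjects (6 HC / 6 PD), one 1 s recording each, default effects."""
    spec = CohortSpec(n_subjects_per_class=6, recordings_per_subject=1,
                      duration_s=1.0, seed=3)
    return generate_cohort(spec)


@pytest.fixture()
def tone_segment():
    """A 1 kHz pure-tone 160 ms segment at 16 kHz."""
    t = np.arange(SEGMENT_LEN) / 16000
    return Segment(samples=0.5 * np.sin(2 * np.pi * 1000 * t),
                   parent_recording="tone/ddk00", start_sample=0,
                   subject_id="tone", label="HC")


@pytest.fixture()
def random_melspec():
    """A random but valid 80x41 dB matrix (values in [-80, 0])."""
    rng = np.random.default_rng(42)
    values = -80.0 * rng.random((N_MELS, N_FRAMES))
    values.flat[rng.integers(0, values.size)] = 0.0
    return MelSpectrogram(values=values, segment_id="r/x@0",
                          subject_id="r", label="PD")


def make_melspec(rng, subject="s0", label="HC"):
    values = -80.0 * rng.random((N_MELS, N_FRAMES))
    return MelSpectrogram(values=values, segment_id=f"{subject}/t@0",
                          subject_id=subject, label=label)


def make_recording(samples, sr=16000, subject="s0", label="HC"):
    return AudioRecording(samples=np.asarray(samples, dtype=float),
                          sample_rate=sr, subject_id=subject, label=label)
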