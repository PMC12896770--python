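"""Data augmentation at waveform and time–frequency level.

Seven operators are provided.  Two act on raw audio before the
spectrogram is computed — additive Gaussian noise x'(t) = x(t) + a*n(t)
and circular time shifting x'(t) = x(t - tau) — and five act on the
80x41 log-mel matrix:

* SpecAugment (SA): axis-spanning rectangular time and frequency masks,
* RandMasking (RM): several randomly placed, variably sized masks,
* RandMix (RMi): random blocks replaced by aligned blocks of another
  same-class sample,
* Cutting Masking (CM): one contiguous region cut-and-pasted from
  another same-class sample,
* Mixture Masking (MM): one region blended as lam*target + (1-lam)*source.

``expand_training_set`` doubles a training partition symmetrically: the
output is the originals plus exactly one augmented copy per original,
with labels unchanged, so class balance is preserved.  Block sources are
always drawn from the same class and labels are never mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, ShapeError
from .melspec import DB_FLOOR, N_FRAMES, N_MELS, MelSpectrogram, compute_melspec
from .preprocess import Segment

logger = logging.getLogger(__name__)

WAVEFORM_TECHNIQUES = ("NOISE", "SHIFT", "WAVEFORM_COMBO")
SPECTROGRAM_TECHNIQUES = ("SA", "RM", "RMI", "CM", "MM")
TECHNIQUES = WAVEFORM_TECHNIQUES + SPECTROGRAM_TECHNIQUES


@dataclass(frozen=True)
class AugmentationConfig:
    """All operator parameters; which ones matter depends on ``technique``."""

    technique: str
    alpha: float = 0.05            # noise intensity, re unit peak
    tau_fraction: float = 0.1      # shift as fraction of signal length
    n_time_masks: int = 1          # SA
    n_freq_masks: int = 1          # SA
    max_mask_frames: int = 8       # SA, frames
    max_mask_bands: int = 12       # SA, mel bands
    n_blocks: int = 3              # RM / RMi
    block_h: int = 16              # max block height, bands
    block_w: int = 10              # max block width, frames
    lambda_mix: float = 0.5        # MM
    source_policy: str = "same_class"
    fill_mode: str = "floor_db"    # or "matrix_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ParameterError(f"unknown technique {self.technique!r}")
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if not 0.0 <= self.tau_fraction < 1.0:
            raise ParameterError("tau_fraction must be in [0, 1)")
        if self.max_mask_bands > N_MELS or self.block_h > N_MELS:
            raise ParameterError("mask/block height exceeds 80 mel bands")
        if self.max_mask_frames > N_FRAMES or self.block_w > N_FRAMES:
            raise ParameterError("mask/block width exceeds 41 frames")
        if min(self.n_time_masks, self.n_freq_masks, self.n_blocks) < 0:
            raise ParameterError("mask/block counts must be >= 0")
        if self.block_h < 1 or self.block_w < 1:
            raise ParameterError("block_h and block_w must be >= 1")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ParameterError("lambda_mix must be in [0, 1]")
        if self.source_policy != "same_class":
            raise ParameterError("source_policy must be 'same_class'")
        if self.fill_mode not in ("floor_db", "matrix_mean"):
            raise ParameterError("fill_mode must be 'floor_db' or 'matrix_mean'")


def config_for(technique: str, seed: int = 0, **overrides) -> AugmentationConfig:
    """Default configuration per technique.

    CM and MM use a single region averaging about a quarter of the
    matrix area; RM/RMi use several smaller blocks; SA uses one time and
    one frequency stripe.
    """
    defaults: dict = {}
    if technique in ("CM", "MM"):
        defaults = {"block_h": N_MELS, "block_w": N_FRAMES}
    defaults.update(overrides)
    return AugmentationConfig(technique=technique, seed=seed, **defaults)


def _rng(cfg: AugmentationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def _fill_value(values: np.ndarray, cfg: AugmentationConfig) -> float:
    return DB_FLOOR if cfg.fill_mode == "floor_db" else float(values.mean())


def _check_shape(S: MelSpectrogram) -> None:
    if S.values.shape != (N_MELS, N_FRAMES):
        raise ShapeError(f"expected {N_MELS}x{N_FRAMES}, got {S.values.shape}")


# ---------------------------------------------------------------- waveform

def additive_noise(x: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """x' = x + alpha * n, n i.i.d. standard Gaussian."""
    x = np.asarray(x, dtype=np.float64)
    if cfg.alpha == 0:
        return x.copy()
    return x + cfg.alpha * _rng(cfg, rng).standard_normal(x.shape)


def time_shift(x: np.ndarray, cfg: AugmentationConfig,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Circular shift by tau = round(tau_fraction * N) samples."""
    x = np.asarray(x, dtype=np.float64)
    tau = int(round(cfg.tau_fraction * len(x)))
    return np.roll(x, tau)


# ------------------------------------------------------------ spectrogram

def spec_augment(S: MelSpectrogram, cfg: AugmentationConfig,
                 rng: np.random.Generator | None = None) -> MelSpectrogram:
    """Axis-spanning time and frequency stripes, widths uniform in [0, max]."""
    _check_shape(S)
    rng = _rng(cfg, rng)
    out = S.values.copy()
    fill = _fill_value(S.values, cfg)
    for _ in range(cfg.n_time_masks):
        w = int(rng.integers(0, cfg.max_mask_frames + 1))
        c0 = int(rng.integers(0, N_FRAMES - w + 1))
        out[:, c0:c0 + w] = fill
    for _ in range(cfg.n_freq_masks):
        h = int(rng.integers(0, cfg.max_mask_bands + 1))
        r0 = int(rng.integers(0, N_MELS - h + 1))
        out[r0:r0 + h, :] = fill
    return replace(S, values=out)


def _random_block(rng: np.random.Generator, cfg: AugmentationConfig):
    h = int(rng.integers(1, cfg.block_h + 1))
    w = int(rng.integers(1, cfg.block_w + 1))
    r0 = int(rng.integers(0, N_MELS - h + 1))
    c0 = int(rng.integers(0, N_FRAMES - w + 1))
    return r0, c0, h, w


def rand_masking(S: MelSpectrogram, cfg: AugmentationConfig,
                 rng: np.random.Generator | None = None) -> MelSpectrogram:
    """n_blocks randomly placed rectangles set to the fill value; overlap allowed."""
    _check_shape(S)
    rng = _rng(cfg, rng)
    out = S.values.copy()
    fill = _fill_value(S.values, cfg)
    for _ in range(cfg.n_blocks):
        r0, c0, h, w = _random_block(rng, cfg)
        out[r0:r0 + h, c0:c0 + w] = fill
    return replace(S, values=out)


def rand_mix(S_target: MelSpectrogram, S_source: MelSpectrogram,
             cfg: AugmentationConfig,
             rng: np.random.Generator | None = None) -> MelSpectrogram:
    """n_blocks rectangles replaced by the aligned cells of the source."""
    _check_shape(S_target)
    _check_shape(S_source)
    rng = _rng(cfg, rng)
    out = S_target.values.copy()
    for _ in range(cfg.n_blocks):
        r0, c0, h, w = _random_block(rng, cfg)
        out[r0:r0 + h, c0:c0 + w] = S_source.values[r0:r0 + h, c0:c0 + w]
    return replace(S_target, values=out)


def cut_masking(S_target: MelSpectrogram, S_source: MelSpectrogram,
                cfg: AugmentationConfig,
                rng: np.random.Generator | None = None) -> MelSpectrogram:
    """One contiguous region cut from the source and pasted onto the target.

    The output keeps the target's label.
    """
    _check_shape(S_target)
    _check_shape(S_source)
    rng = _rng(cfg, rng)
    out = S_target.values.copy()
    r0, c0, h, w = _random_block(rng, cfg)
    out[r0:r0 + h, c0:c0 + w] = S_source.values[r0:r0 + h, c0:c0 + w]
    return replace(S_target, values=out)


def mixture_masking(S_target: MelSpectrogram, S_source: MelSpectrogram,
                    cfg: AugmentationConfig,
                    rng: np.random.Generator | None = None) -> MelSpectrogram:
    """One region blended as lam*target + (1-lam)*source; outside unchanged."""
    _check_shape(S_target)
    _check_shape(S_source)
    lam = cfg.lambda_mix
    rng = _rng(cfg, rng)
    out = S_target.values.copy()
    r0, c0, h, w = _random_block(rng, cfg)
    out[r0:r0 + h, c0:c0 + w] = (lam * S_target.values[r0:r0 + h, c0:c0 + w]
                                 + (1 - lam) * S_source.values[r0:r0 + h, c0:c0 + w])
    return replace(S_target, values=out)


# ------------------------------------------------------------- expansion

_NEEDS_SOURCE = {"RMI", "CM", "MM"}


def _to_melspec(item: Segment | MelSpectrogram) -> MelSpectrogram:
    return item if isinstance(item, MelSpectrogram) else compute_melspec(item)


def _augment_one(item: Segment | MelSpectrogram, base: MelSpectrogram,
                 cfgs: list[AugmentationConfig], source: MelSpectrogram | None,
                 rng: np.random.Generator) -> MelSpectrogram:
    waveform_cfgs = [c for c in cfgs if c.technique in WAVEFORM_TECHNIQUES]
    spec_cfgs = [c for c in cfgs if c.technique in SPECTROGRAM_TECHNIQUES]
    if waveform_cfgs:
        if not isinstance(item, Segment):
            raise ParameterError(
                "waveform-level techniques require Segment inputs")
        x = item.samples
        for cfg in waveform_cfgs:
            if cfg.technique in ("NOISE", "WAVEFORM_COMBO"):
                x = additive_noise(x, cfg, rng)
            if cfg.technique in ("SHIFT", "WAVEFORM_COMBO"):
                x = time_shift(x, cfg, rng)
        S = compute_melspec(replace(item, samples=x))
    else:
        S = replace(base, values=base.values.copy())
    for cfg in spec_cfgs:
        if cfg.technique == "SA":
            S = spec_augment(S, cfg, rng)
        elif cfg.technique == "RM":
            S = rand_masking(S, cfg, rng)
        elif cfg.technique == "RMI":
            S = rand_mix(S, source, cfg, rng)
        elif cfg.technique == "CM":
            S = cut_masking(S, source, cfg, rng)
        elif cfg.technique == "MM":
            S = mixture_masking(S, source, cfg, rng)
    return replace(S, segment_id=S.segment_id + "+aug")


def expand_training_set(items, cfgs) -> list[MelSpectrogram]:
    """Double a training partition: originals plus one augmented copy each.

    ``items`` may be :class:`Segment` objects (required for waveform-level
    techniques) or :class:`MelSpectrogram` objects; ``cfgs`` is one
    configuration or a list composed in order.  Block-source techniques
    draw their source uniformly from the other same-class items of the
    batch; an item whose class has no other member passes through
    unaugmented (logged).  Returns ``2 * len(items)`` spectrograms with
    labels preserved.
    """
    if isinstance(cfgs, AugmentationConfig):
        cfgs = [cfgs]
    if not items:
        return []
    originals = [_to_melspec(it) for it in items]
    needs_source = any(c.technique in _NEEDS_SOURCE for c in cfgs)
    by_class: dict[str, list[int]] = {}
    for i, S in enumerate(originals):
        by_class.setdefault(S.label, []).append(i)
    base_seed = cfgs[0].seed if cfgs else 0
    augmented: list[MelSpectrogram] = []
    for i, (item, S) in enumerate(zip(items, originals)):
        rng = np.random.default_rng(np.random.SeedSequence((base_seed, i)))
        source = None
        if needs_source:
            pool = [j for j in by_class[S.label] if j != i]
            if not pool:
                logger.warning("item %d (%s): no same-class source; passed "
                               "through unaugmented", i, S.label)
                augmented.append(replace(S, values=S.values.copy(),
                                         segment_id=S.segment_id + "+aug"))
                continue
            source = originals[pool[int(rng.integers(0, len(pool)))]]
        augmented.append(_augment_one(item, S, cfgs, source, rng))
    return originals + augmented
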