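"""Augmentation operators: identity limits, geometry, statistics, doubling."""

import numpy as np
import pytest

from ddkaug.augment import (AugmentationConfig, additive_noise, config_for,
                            cut_masking, expand_training_set, mixture_masking,
                            rand_masking, rand_mix, spec_augment, time_shift)
from ddkaug.errors import ParameterError
from ddkaug.melspec import DB_FLOOR, N_FRAMES, N_MELS
from ddkaug.preprocess import SEGMENT_LEN, Segment
from tests.conftest import make_melspec


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def _cfg(**kw):
    kw.setdefault("technique", "SA")
    return AugmentationConfig(**kw)


class TestWaveformOps:
    def test_alpha_zero_identity(self, rng):
        x = rng.normal(size=1000)
        np.testing.assert_array_equal(additive_noise(x, _cfg(technique="NOISE",
                                                             alpha=0.0)), x)

    def test_noise_formula(self):
        cfg = _cfg(technique="NOISE", alpha=0.1, seed=9)
        x = np.array([1.0, 0.0, -1.0])
        out = additive_noise(x, cfg)
        n = np.random.default_rng(9).standard_normal(3)
        np.testing.assert_allclose(out, x + 0.1 * n)

    def test_empirical_snr_near_20db(self):
        # unit-power signal, alpha=0.1 -> SNR = 10 log10(1 / (0.01 P_n)) ~ 20 dB
        rng = np.random.default_rng(1)
        x = np.sqrt(2) * np.sin(2 * np.pi * 440 * np.arange(16000) / 16000)
        cfg = _cfg(technique="NOISE", alpha=0.1, seed=2)
        noise = additive_noise(x, cfg) - x
        snr = 10 * np.log10(np.mean(x ** 2) / np.mean(noise ** 2))
        assert abs(snr - 20.0) <= 1.0

    def test_tau_zero_identity(self, rng):
        x = rng.normal(size=500)
        np.testing.assert_array_equal(
            time_shift(x, _cfg(technique="SHIFT", tau_fraction=0.0)), x)

    def test_circularity_two_half_shifts(self, rng):
        x = rng.normal(size=500)
        half = _cfg(technique="SHIFT", tau_fraction=0.5)
        np.testing.assert_array_equal(time_shift(time_shift(x, half), half), x)

    def test_multiset_preserved_and_xcorr_peak_at_tau(self, rng):
        x = rng.normal(size=400)
        cfg = _cfg(technique="SHIFT", tau_fraction=0.25)
        out = time_shift(x, cfg)
        assert sorted(out) == sorted(x)
        # circular cross-correlation argmax equals tau
        xc = np.fft.ifft(np.fft.fft(out) * np.conj(np.fft.fft(x))).real
        assert int(np.argmax(xc)) == 100


class TestSpecAugment:
    def test_zero_masks_identity(self, random_melspec):
        cfg = _cfg(n_time_masks=0, n_freq_masks=0)
        out = spec_augment(random_melspec, cfg)
        np.testing.assert_array_equal(out.values, random_melspec.values)

    def test_time_mask_spans_all_bands(self, random_melspec, rng):
        cfg = _cfg(n_time_masks=1, n_freq_masks=0, max_mask_frames=8)
        out = spec_augment(random_melspec, cfg, rng)
        changed = out.values != random_melspec.values
        n_changed = changed.sum()
        assert n_changed % N_MELS == 0           # full-height stripes
        assert n_changed <= 8 * N_MELS
        # unmasked cells bit-identical
        assert np.array_equal(out.values[~changed],
                              random_melspec.values[~changed])

    def test_masked_fraction_matches_uniform_mean(self, random_melspec):
        # E[width] = max/2 for width ~ U{0..max}; fraction = E[w]/41
        max_w = 8
        cfg = _cfg(n_time_masks=1, n_freq_masks=0, max_mask_frames=max_w)
        rng = np.random.default_rng(7)
        fractions = []
        base = random_melspec.values
        for _ in range(10_000):
            out = spec_augment(random_melspec, cfg, rng)
            fractions.append(np.mean(out.values != base))
        expected = (max_w / 2) / N_FRAMES
        # masking can coincide with equal values only at measure zero here
        assert abs(np.mean(fractions) - expected) < 0.01

    def test_oversized_mask_rejected(self):
        with pytest.raises(ParameterError):
            _cfg(max_mask_frames=42)
        with pytest.raises(ParameterError):
            _cfg(max_mask_bands=81)


class TestRandMasking:
    def test_zero_blocks_identity(self, random_melspec):
        cfg = _cfg(technique="RM", n_blocks=0)
        out = rand_masking(random_melspec, cfg)
        np.testing.assert_array_equal(out.values, random_melspec.values)

    def test_changed_cells_equal_fill_and_bounded(self, random_melspec, rng):
        cfg = _cfg(technique="RM", n_blocks=3, block_h=16, block_w=10)
        out = rand_masking(random_melspec, cfg, rng)
        changed = out.values != random_melspec.values
        assert np.all(out.values[changed] == DB_FLOOR)
        assert changed.sum() <= 3 * 16 * 10

    def test_matrix_mean_fill(self, random_melspec, rng):
        cfg = _cfg(technique="RM", n_blocks=1, fill_mode="matrix_mean")
        out = rand_masking(random_melspec, cfg, rng)
        changed = out.values != random_melspec.values
        np.testing.assert_allclose(out.values[changed],
                                   random_melspec.values.mean())


class TestBlockSourceOps:
    def test_identical_source_identity(self, random_melspec, rng):
        for op in (rand_mix, cut_masking):
            out = op(random_melspec, random_melspec,
                     _cfg(technique="CM"), rng)
            np.testing.assert_array_equal(out.values, random_melspec.values)

    def test_partition_property(self, rng):
        target, source = make_melspec(rng, "a"), make_melspec(rng, "b")
        out = rand_mix(target, source, _cfg(technique="RMI", n_blocks=4), rng)
        from_target = out.values == target.values
        from_source = out.values == source.values
        assert np.all(from_target | from_source)

    def test_full_block_replacement(self, rng):
        # an rng stub that always draws the maximal block forces an 80x41
        # region, so the output must equal the source everywhere
        class _MaxRng:
            def integers(self, low, high):
                return high - 1

        target, source = make_melspec(rng, "a"), make_melspec(rng, "b")
        cfg = _cfg(technique="RMI", n_blocks=1, block_h=N_MELS, block_w=N_FRAMES)
        out = rand_mix(target, source, cfg, _MaxRng())
        np.testing.assert_array_equal(out.values, source.values)

    def test_cut_region_exact_and_complement_identical(self, rng):
        target, source = make_melspec(rng, "a"), make_melspec(rng, "b")
        out = cut_masking(target, source, config_for("CM"), rng)
        changed = out.values != target.values
        rows, cols = np.nonzero(changed)
        r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
        np.testing.assert_array_equal(out.values[r0:r1 + 1, c0:c1 + 1],
                                      source.values[r0:r1 + 1, c0:c1 + 1])
        assert np.array_equal(out.values[~changed], target.values[~changed])
        assert out.label == target.label

    def test_cut_region_area_matches_expectation(self, rng):
        cfg = config_for("CM")   # h ~ U{1..80}, w ~ U{1..41}
        target, source = make_melspec(rng, "a"), make_melspec(rng, "b")
        fractions = []
        for _ in range(10_000):
            out = cut_masking(target, source, cfg, rng)
            fractions.append(np.mean(out.values != target.values))
        expected = ((cfg.block_h + 1) / 2) * ((cfg.block_w + 1) / 2) / (80 * 41)
        assert abs(np.mean(fractions) - expected) < 0.01

    def test_mixture_limits_and_mean(self, rng):
        target, source = make_melspec(rng, "a"), make_melspec(rng, "b")
        out1 = mixture_masking(target, source,
                               config_for("MM", lambda_mix=1.0), rng)
        np.testing.assert_array_equal(out1.values, target.values)
        out0 = mixture_masking(target, source,
                               config_for("MM", lambda_mix=0.0),
                               np.random.default_rng(5))
        changed = out0.values != target.values
        assert np.array_equal(out0.values[changed], source.values[changed])
        outh = mixture_masking(target, source,
                               config_for("MM", lambda_mix=0.5),
                               np.random.default_rng(5))
        np.testing.assert_allclose(
            outh.values[changed],
            0.5 * target.values[changed] + 0.5 * source.values[changed])

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ParameterError):
            config_for("MM", lambda_mix=1.5)


class TestExpandTrainingSet:
    def _items(self, n_pd=5, n_hc=5, seed=0):
        rng = np.random.default_rng(seed)
        items = [make_melspec(rng, f"pd{i}", "PD") for i in range(n_pd)]
        items += [make_melspec(rng, f"hc{i}", "HC") for i in range(n_hc)]
        return items

    def test_doubles_with_class_balance(self):
        out = expand_training_set(self._items(), config_for("CM", seed=1))
        assert len(out) == 20
        assert sum(s.label == "PD" for s in out) == 10
        assert sum(s.label == "HC" for s in out) == 10

    def test_empty_input(self):
        assert expand_training_set([], config_for("SA")) == []

    def test_combo_deterministic(self):
        cfgs = [config_for("CM", seed=6), config_for("SA", seed=6)]
        a = expand_training_set(self._items(), cfgs)
        b = expand_training_set(self._items(), cfgs)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_singleton_class_passes_through(self, caplog):
        items = self._items(n_pd=1, n_hc=3)
        out = expand_training_set(items, config_for("CM", seed=2))
        assert len(out) == 8
        aug_pd = [s for s in out[4:] if s.label == "PD"]
        np.testing.assert_array_equal(aug_pd[0].values, items[0].values)

    def test_waveform_technique_requires_segments(self):
        with pytest.raises(ParameterError, match="waveform"):
            expand_training_set(self._items(),
                                config_for("NOISE", seed=0))

    def test_waveform_combo_on_segments(self):
        rng = np.random.default_rng(8)
        segs = [Segment(samples=rng.normal(size=SEGMENT_LEN),
                        parent_recording=f"s{i}/t", start_sample=0,
                        subject_id=f"s{i}", label="PD" if i % 2 else "HC")
                for i in range(4)]
        out = expand_training_set(segs, config_for("WAVEFORM_COMBO", seed=3))
        assert len(out) == 8
        assert all(o.values.shape == (80, 41) for o in out)
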