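"""Luminance channels, histograms, and FFT bandpass pattern spectra."""

import numpy as np
import pytest

from nestcamo.metrics import (bandpass_bank, contrast, luminance_diff,
                              luminance_histogram, luminance_image,
                              mean_luminance, pattern_diff, pattern_spectrum,
                              PatternSpectrum)
from nestcamo.vision import ConeCatchImage, builtin_visual_system

SQRT2 = np.sqrt(2)


def cone_image(system_name, **channels):
    system = builtin_visual_system(system_name)
    return ConeCatchImage(channels={k: np.asarray(v, dtype=float)
                                    for k, v in channels.items()},
                          system=system)


class TestLuminanceChannel:
    def test_ferret_uses_l_cone(self):
        cone = cone_image("ferret", s=np.full((4, 4), 0.9),
                          l=np.full((4, 4), 0.3))
        np.testing.assert_allclose(luminance_image(cone).values, 0.3)

    def test_human_is_lm_average(self):
        cone = cone_image("human", s=np.zeros((4, 4)),
                          m=np.full((4, 4), 0.4), l=np.full((4, 4), 0.2))
        np.testing.assert_allclose(luminance_image(cone).values, 0.3)

    def test_peafowl_uses_double_cone(self):
        dbl = np.linspace(0, 1, 16).reshape(4, 4)
        cone = cone_image("peafowl", u=np.ones((4, 4)), s=np.ones((4, 4)),
                          m=np.ones((4, 4)), l=np.ones((4, 4)), dbl=dbl)
        np.testing.assert_allclose(luminance_image(cone).values, dbl)

    def test_missing_channel_rejected(self):
        cone = cone_image("ferret", s=np.ones((4, 4)), l=np.ones((4, 4)))
        del cone.channels["l"]
        with pytest.raises(ValueError, match="luminance"):
            luminance_image(cone)


class TestMeanAndContrast:
    def test_uniform_mean_is_sqrt(self):
        lum = np.full((6, 6), 0.25)
        assert mean_luminance(lum, np.ones((6, 6), bool)) == pytest.approx(0.5)

    def test_two_level_mean(self):
        lum = np.concatenate([np.full(8, 0.04), np.full(8, 0.16)]).reshape(4, 4)
        assert mean_luminance(lum, np.ones((4, 4), bool)) == pytest.approx(0.3)

    def test_two_level_contrast(self):
        lum = np.concatenate([np.full(8, 0.04), np.full(8, 0.16)]).reshape(4, 4)
        assert contrast(lum, np.ones((4, 4), bool)) == pytest.approx(0.1)

    def test_uniform_contrast_zero(self):
        assert contrast(np.full((4, 4), 0.3), np.ones((4, 4), bool)) == 0.0

    def test_contrast_sqrt_homogeneity(self, rng):
        lum = rng.uniform(0.1, 0.9, size=(8, 8))
        mask = np.ones((8, 8), bool)
        assert contrast(lum * 0.25, mask) == pytest.approx(
            0.5 * contrast(lum, mask))

    def test_permutation_invariant(self, rng):
        lum = rng.uniform(0, 1, size=(6, 6))
        mask = np.ones((6, 6), bool)
        shuffled = rng.permutation(lum.ravel()).reshape(6, 6)
        assert mean_luminance(lum, mask) == pytest.approx(
            mean_luminance(shuffled, mask))
        assert contrast(lum, mask) == pytest.approx(contrast(shuffled, mask))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_luminance(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestLuminanceHistogram:
    def test_uniform_half_fills_bin_16(self):
        hist = luminance_histogram(np.full((4, 4), 0.5), np.ones((4, 4), bool))
        assert hist[16] == 1.0
        assert hist.sum() == pytest.approx(1.0)

    def test_two_patch_binning(self):
        lum = np.concatenate([np.full(8, 0.1), np.full(8, 0.9)]).reshape(4, 4)
        hist = luminance_histogram(lum, np.ones((4, 4), bool))
        assert hist[3] == 0.5 and hist[28] == 0.5

    def test_values_above_one_go_to_top_bin(self):
        hist = luminance_histogram(np.full((4, 4), 1.3), np.ones((4, 4), bool))
        assert hist[31] == 1.0

    def test_proportions_sum_to_one(self, rng):
        lum = rng.uniform(0, 1.2, size=(9, 9))
        hist = luminance_histogram(lum, rng.uniform(size=(9, 9)) > 0.4)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)


class TestLuminanceDiff:
    def test_identical_histograms_zero(self, rng):
        h = rng.dirichlet(np.ones(32))
        assert luminance_diff(h, h) == 0.0

    def test_disjoint_histograms_two(self):
        a = np.zeros(32)
        b = np.zeros(32)
        a[0] = 1.0
        b[31] = 1.0
        assert luminance_diff(a, b) == 2.0

    def test_half_overlap_example(self):
        a = np.zeros(32)
        a[0] = 1.0
        b = np.zeros(32)
        b[0] = b[1] = 0.5
        assert luminance_diff(a, b) == pytest.approx(1.0)

    def test_l1_metric_axioms(self, rng):
        h1, h2, h3 = (rng.dirichlet(np.ones(32)) for _ in range(3))
        assert luminance_diff(h1, h2) == pytest.approx(luminance_diff(h2, h1))
        assert luminance_diff(h1, h3) <= (luminance_diff(h1, h2)
                                          + luminance_diff(h2, h3) + 1e-12)


class TestBandpassBank:
    def test_default_is_17_scales_2_to_512(self):
        scales = bandpass_bank()
        assert len(scales) == 17
        assert scales[0] == 2.0
        assert scales[-1] == pytest.approx(512.0)

    def test_small_max_scale(self):
        np.testing.assert_allclose(bandpass_bank(4), [2, 2 * SQRT2, 4])

    def test_consecutive_ratio_is_sqrt2(self):
        scales = bandpass_bank()
        np.testing.assert_allclose(np.diff(np.log(scales)), np.log(SQRT2),
                                   atol=1e-12)


class TestPatternSpectrum:
    def test_constant_region_has_zero_energy(self):
        spec = pattern_spectrum(np.full((32, 32), 0.4), np.ones((32, 32), bool))
        np.testing.assert_allclose(spec.energies, 0, atol=1e-12)

    def test_sinusoid_energy_lands_in_its_band(self):
        x = np.arange(64)
        lum = 0.5 + 0.4 * np.sin(2 * np.pi * x / 8)[None, :] * np.ones((64, 1))
        spec = pattern_spectrum(lum, np.ones((64, 64), bool))
        band8 = int(np.argmin(np.abs(spec.scales - 8)))
        others = np.delete(spec.energies, band8)
        assert spec.energies[band8] >= 10 * others.max()

    def test_total_energy_matches_parseval(self):
        # in-band signal: sum of two sinusoids at periods 8 and 16
        x = np.arange(64)
        lum = (0.5 + 0.2 * np.sin(2 * np.pi * x / 8)[None, :]
               + 0.2 * np.cos(2 * np.pi * x / 16)[:, None])
        mask = np.ones((64, 64), bool)
        spec = pattern_spectrum(lum, mask)
        total = np.sqrt((spec.energies ** 2).sum())
        assert total == pytest.approx(lum.std(), rel=0.05)

    def test_translation_invariance_for_periodic_texture(self):
        x = np.arange(64)
        lum = 0.5 + 0.3 * np.sin(2 * np.pi * x / 8)[None, :] * np.ones((64, 1))
        mask = np.ones((64, 64), bool)
        e0 = pattern_spectrum(lum, mask).energies
        e1 = pattern_spectrum(np.roll(lum, 3, axis=1), mask).energies
        nz = e0 > 1e-9
        assert np.all(np.abs(e1[nz] - e0[nz]) / e0[nz] < 0.02)

    def test_tiny_region_rejected(self):
        mask = np.zeros((32, 32), bool)
        mask[:3, :3] = True
        with pytest.raises(ValueError, match="4×4"):
            pattern_spectrum(np.ones((32, 32)), mask)

    def test_scales_beyond_crop_report_zero(self):
        spec = pattern_spectrum(np.random.default_rng(0).uniform(size=(16, 16)),
                                np.ones((16, 16), bool))
        assert len(spec.scales) == 17
        beyond = spec.scales > 16 * SQRT2
        np.testing.assert_allclose(spec.energies[beyond], 0, atol=1e-12)


class TestPatternDiff:
    def test_identical_spectra_zero(self, rng):
        e = rng.uniform(size=17)
        s = PatternSpectrum(bandpass_bank(), e)
        assert pattern_diff(s, s) == 0.0

    def test_non_overlapping_sinusoids_sum(self):
        x = np.arange(64)
        mask = np.ones((64, 64), bool)
        t = 0.5 + 0.3 * np.sin(2 * np.pi * x / 8)[None, :] * np.ones((64, 1))
        b = 0.5 + 0.3 * np.sin(2 * np.pi * x / 32)[None, :] * np.ones((64, 1))
        st, sb = pattern_spectrum(t, mask), pattern_spectrum(b, mask)
        i8 = int(np.argmin(np.abs(st.scales - 8)))
        i32 = int(np.argmin(np.abs(st.scales - 32)))
        expected = st.energies[i8] + sb.energies[i32]
        assert pattern_diff(st, sb) == pytest.approx(expected, rel=0.02)

    def test_triangle_inequality(self, rng):
        scales = bandpass_bank()
        s1, s2, s3 = (PatternSpectrum(scales, rng.uniform(size=17))
                      for _ in range(3))
        assert pattern_diff(s1, s3) <= (pattern_diff(s1, s2)
                                        + pattern_diff(s2, s3) + 1e-12)
        assert pattern_diff(s1, s2) == pytest.approx(pattern_diff(s2, s1))

    def test_mismatched_scales_rejected(self):
        s1 = PatternSpectrum(bandpass_bank(), np.zeros(17))
        s2 = PatternSpectrum(bandpass_bank(4), np.zeros(3))
        with pytest.raises(ValueError, match="scale"):
            pattern_diff(s1, s2)
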