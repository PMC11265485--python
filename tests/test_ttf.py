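"""Circular-edge task transfer function: center finding, ESF, TTF, f50."""

import numpy as np
import pytest
from scipy import integrate, special

import ctiq
from ctiq import (NoiseModel, calibrate_shape, esf_to_ttf, find_center,
                  gaussian_f50, lesion_slice_mask, measure_ttf, radial_esf,
                  simulate_scan, ttf_average)
from ctiq.ttf import _first_half_crossing

LESION_R = 7.5  # mm


def blurred_disk_profile(r, sigma, radius=LESION_R):
    """Analytic radial profile of a disk convolved with a 2D Gaussian.

    Independent oracle: 1D Bessel integral (Rice/Marcum form), evaluated by
    adaptive quadrature with the exponentially scaled I0 for stability.
    """
    def f(s):
        x = r * s / sigma ** 2
        return (s / sigma ** 2) * np.exp(
            -(s * s + r * r) / (2 * sigma ** 2) + x) * special.i0e(x)
    return integrate.quad(f, 0.0, radius, limit=200)[0]


def noiseless_stack(layout, sigma_psf, n_slices=14):
    model = NoiseModel("nl", sigma_ref=0.0, edge_blur_sigma=sigma_psf)
    return simulate_scan(layout, model, 25.0, 2.5, n_slices, seed=1)


class TestFindCenter:
    def test_noiseless_center_within_fifth_pixel(self, small_layout):
        stack = noiseless_stack(small_layout, 0.6)
        s = small_layout.pixel_spacing
        ny, nx = small_layout.grid_size
        true_row = small_layout.lc_center_mm[1] / s + ny / 2.0 - 0.5
        true_col = small_layout.lc_center_mm[0] / s + nx / 2.0 - 0.5
        mask = lesion_slice_mask(small_layout, 14, 2.5)
        img = stack.voxels[np.nonzero(mask)[0]].mean(axis=0)
        row, col = find_center(img, (true_row, true_col), LESION_R / s)
        assert abs(row - true_row) < 0.2 and abs(col - true_col) < 0.2

    def test_rotation_invariance(self):
        """Centroid of a centered symmetric lesion survives a 90-deg rotation."""
        n = 101
        rr, cc = np.mgrid[0:n, 0:n]
        img = 55.0 + 25.0 * (np.hypot(rr - 50, cc - 50) <= 10)
        c0 = find_center(img, (50, 50), 10)
        c1 = find_center(np.rot90(img), (50, 50), 10)
        assert c0 == pytest.approx((50.0, 50.0), abs=1e-9)
        assert c1 == pytest.approx(c0, abs=1e-9)

    def test_absent_lesion_rejected(self):
        img = np.full((64, 64), 55.0)
        with pytest.raises(ValueError, match="contrast"):
            find_center(img, (32, 32), 10)


class TestRadialEsf:
    def test_unblurred_step_at_lesion_radius(self, small_layout):
        stack = noiseless_stack(small_layout, 0.0)
        s = small_layout.pixel_spacing
        mask = lesion_slice_mask(small_layout, 14, 2.5)
        slices = stack.voxels[np.nonzero(mask)[0]]
        ny, nx = small_layout.grid_size
        center = (small_layout.lc_center_mm[1] / s + ny / 2.0 - 0.5,
                  small_layout.lc_center_mm[0] / s + nx / 2.0 - 0.5)
        r, esf = radial_esf(slices, center, s, 1.8 * LESION_R)
        assert esf[0] == pytest.approx(80.0, abs=0.5)
        assert esf[-1] == pytest.approx(55.0, abs=0.5)
        crossing = r[np.nonzero(esf < 67.5)[0][0]]
        bin_w = r[1] - r[0]
        assert abs(crossing - LESION_R) <= 1.5 * bin_w

    @pytest.mark.parametrize("sigma", [0.6, 0.8])
    def test_matches_analytic_blurred_disk(self, small_layout, sigma):
        """Measured ESF tracks the Bessel-integral oracle within 0.5 HU RMS."""
        stack = noiseless_stack(small_layout, sigma)
        s = small_layout.pixel_spacing
        mask = lesion_slice_mask(small_layout, 14, 2.5)
        slices = stack.voxels[np.nonzero(mask)[0]]
        ny, nx = small_layout.grid_size
        approx = (small_layout.lc_center_mm[1] / s + ny / 2.0 - 0.5,
                  small_layout.lc_center_mm[0] / s + nx / 2.0 - 0.5)
        center = find_center(slices.mean(axis=0), approx, LESION_R / s)
        r, esf = radial_esf(slices, center, s, 1.8 * LESION_R)
        oracle = 55.0 + 25.0 * np.array(
            [blurred_disk_profile(ri, sigma) for ri in r])
        assert np.sqrt(np.mean((esf - oracle) ** 2)) < 0.5

    def test_pure_noise_esf_flat(self):
        rng = np.random.default_rng(0)
        field = rng.normal(0.0, 5.0, (10, 128, 128))
        r, esf = radial_esf(field, (63.5, 63.5), 0.6854, 13.5)
        assert esf.std() < 2.5  # sampling scatter only, no structure

    def test_too_many_empty_bins_rejected(self):
        img = np.zeros((64, 64))
        with pytest.raises(ValueError, match="bin"):
            radial_esf(img, (32, 32), 0.6854, 10.0, bin_width=0.01)


class TestEsfToTtf:
    @pytest.mark.parametrize("sigma", [0.5, 0.6, 0.8])
    def test_gaussian_closed_form_within_5pct(self, small_layout, sigma):
        stack = noiseless_stack(small_layout, sigma)
        res = measure_ttf(stack, small_layout)
        assert res.f50 == pytest.approx(gaussian_f50(sigma), rel=0.05)

    def test_doubling_blur_halves_f50(self, small_layout):
        f_a = measure_ttf(noiseless_stack(small_layout, 0.45), small_layout).f50
        f_b = measure_ttf(noiseless_stack(small_layout, 0.9), small_layout).f50
        assert f_a / f_b == pytest.approx(2.0, rel=0.08)

    def test_f50_monotone_in_blur(self, small_layout):
        f50s = [measure_ttf(noiseless_stack(small_layout, s), small_layout).f50
                for s in (0.3, 0.6, 1.2)]
        assert f50s[0] > f50s[1] > f50s[2]

    def test_ttf_normalized_at_zero_frequency(self, noiseless_blurred_stack,
                                              small_layout):
        res = measure_ttf(noiseless_blurred_stack, small_layout)
        assert res.ttf[0] == pytest.approx(1.0)
        assert res.contrast == pytest.approx(25.0, abs=1.0)

    def test_polarity_and_offset_invariance(self, small_layout):
        """f50 is identical for hyper/hypo lesions and under HU offsets."""
        stack = noiseless_stack(small_layout, 0.6)
        s = small_layout.pixel_spacing
        mask = lesion_slice_mask(small_layout, 14, 2.5)
        slices = stack.voxels[np.nonzero(mask)[0]]
        ny, nx = small_layout.grid_size
        center = (small_layout.lc_center_mm[1] / s + ny / 2.0 - 0.5,
                  small_layout.lc_center_mm[0] / s + nx / 2.0 - 0.5)
        r, esf = radial_esf(slices, center, s, 1.8 * LESION_R)
        f_hyper = esf_to_ttf(r, esf).f50
        f_hypo = esf_to_ttf(r, -esf + 110.0).f50
        f_shift = esf_to_ttf(r, esf + 500.0).f50
        assert f_hypo == pytest.approx(f_hyper, rel=1e-9)
        assert f_shift == pytest.approx(f_hyper, rel=1e-9)

    def test_unblurred_ttf_bounds_blurred(self, small_layout):
        sharp = measure_ttf(noiseless_stack(small_layout, 0.0), small_layout)
        blurred = measure_ttf(noiseless_stack(small_layout, 0.8), small_layout)
        band = blurred.freq_axis <= 1.0
        assert np.all(sharp.ttf[band] + 0.02 >= blurred.ttf[band])

    def test_f50_not_reached_reported_as_none(self):
        freq = np.linspace(0, 1, 50)
        assert _first_half_crossing(freq, np.full(50, 0.9)) is None

    def test_zero_contrast_rejected(self):
        r = np.arange(20) * 0.17
        with pytest.raises(ValueError, match="contrast"):
            esf_to_ttf(r, np.zeros(20))


class TestNoiseRobustness:
    def test_mean_f50_stable_under_noise(self, small_layout, fbp_shape,
                                         noiseless_blurred_stack):
        """Mean f50 over 50 noisy repeats stays within 10% of noiseless."""
        truth = measure_ttf(noiseless_blurred_stack, small_layout).f50
        model = NoiseModel("n", sigma_ref=8.0, edge_blur_sigma=0.6,
                          nps_shape=fbp_shape)
        f50s = []
        for k in range(50):
            stack = simulate_scan(small_layout, model, 25.0, 2.5, 14,
                                  seed=40000 + k)
            f50s.append(measure_ttf(stack, small_layout, monotone=True).f50)
        assert np.mean(f50s) == pytest.approx(truth, rel=0.10)


class TestTtfAverage:
    def test_identity_and_bounds(self, small_layout, noiseless_blurred_stack):
        res = measure_ttf(noiseless_blurred_stack, small_layout)
        avg = ttf_average([res, res, res])
        np.testing.assert_allclose(avg.ttf, res.ttf)
        assert avg.f50 == pytest.approx(res.f50)
        other = measure_ttf(noiseless_stack(small_layout, 0.3), small_layout)
        mixed = ttf_average([res, other])
        lo = np.minimum(res.ttf, other.ttf) - 1e-12
        hi = np.maximum(res.ttf, other.ttf) + 1e-12
        assert np.all((mixed.ttf >= lo) & (mixed.ttf <= hi))

    def test_axis_mismatch_rejected(self, small_layout, noiseless_blurred_stack):
        res = measure_ttf(noiseless_blurred_stack, small_layout)
        import dataclasses
        shifted = dataclasses.replace(res, freq_axis=res.freq_axis * 1.5)
        with pytest.raises(ValueError, match="axes"):
            ttf_average([res, shifted])

    def test_curve_averaging_beats_median_single(self, small_layout, fbp_shape,
                                                 noiseless_blurred_stack):
        """Averaging TTF curves over 3 repeats improves f50 accuracy (RMSE)
        relative to the median single-scan f50, and wins more often than not."""
        truth = measure_ttf(noiseless_blurred_stack, small_layout).f50
        model = NoiseModel("n", sigma_ref=4.0, edge_blur_sigma=0.6,
                           nps_shape=fbp_shape)
        err_avg, err_med, wins = [], [], 0
        n_trials = 30
        for tr in range(n_trials):
            singles = [measure_ttf(
                simulate_scan(small_layout, model, 25.0, 2.5, 14,
                              seed=90000 + 10 * tr + rep),
                small_layout, monotone=True) for rep in range(3)]
            fa = ttf_average(singles).f50
            med = float(np.median([r.f50 for r in singles]))
            err_avg.append(abs(fa - truth))
            err_med.append(abs(med - truth))
            wins += abs(fa - truth) <= abs(med - truth)
        assert np.sqrt(np.mean(np.square(err_avg))) < np.sqrt(
            np.mean(np.square(err_med)))
        assert wins / n_trials > 0.5
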