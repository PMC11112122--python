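"""MPS autocorrelation, patch detection, AIS length measurement."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf

from axotraffic.ais import (
    AutocorrCurve,
    IntensityProfile,
    PatchDetectParams,
    autocorrelate_profile,
    average_autocorr,
    detect_patches,
    estimate_period,
    measure_ais_length,
    patch_stats,
)
from axotraffic.errors import DegenerateInputError, InputError
from axotraffic.synthetic import (
    simulate_ais_image,
    simulate_ais_marker_profile,
    simulate_mps_profile,
)


class TestAutocorrelation:
    def test_cosine_maxima_at_multiples_of_period(self):
        T = 20  # px
        x = np.arange(400)
        p = IntensityProfile(np.cos(2 * np.pi * x / T), px_nm=30.0)
        c = autocorrelate_profile(p, max_lag_nm=50 * 30.0)
        lags_px = np.arange(len(c.values))
        for mult in (1, 2):
            window = c.values[(lags_px >= mult * T - 2) & (lags_px <= mult * T + 2)]
            assert np.argmax(window) == 2  # peak centered at mult*T
        assert c.values[0] == pytest.approx(1.0)

    def test_normalized_and_bounded_on_random_profiles(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(40, 200))
            p = IntensityProfile(rng.uniform(0, 100, n), px_nm=30.0)
            c = autocorrelate_profile(p, max_lag_nm=(n // 2) * 30.0)
            assert c.values[0] == pytest.approx(1.0)
            assert np.all(np.abs(c.values) <= 1.0 + 1e-12)

    def test_constant_profile_degenerate(self):
        with pytest.raises(DegenerateInputError):
            autocorrelate_profile(IntensityProfile(np.full(100, 3.0), 30.0), 300)

    def test_synthetic_lattice_side_peak(self):
        p = simulate_mps_profile(spacing_nm=190, px_nm=30, length_um=10, noise_frac=0.1, seed=0)
        c = autocorrelate_profile(p, max_lag_nm=600)
        assert estimate_period(c) == pytest.approx(180.0)  # 190 nm snapped to the 30 nm grid


class TestAverageAutocorr:
    def _curve(self, values):
        return AutocorrCurve(lags_nm=np.arange(len(values)) * 30.0, values=values)

    def test_identical_curves(self):
        c = self._curve(np.linspace(1, 0, 10))
        mean, sem = average_autocorr([c, c, c])
        np.testing.assert_allclose(mean.values, c.values)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_two_curve_mean(self):
        a = self._curve(np.linspace(1, 0, 10))
        b = self._curve(np.linspace(1, -0.5, 10))
        mean, _ = average_autocorr([a, b])
        np.testing.assert_allclose(mean.values, (a.values + b.values) / 2)

    def test_sem_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        def sem_of(n):
            curves = [
                autocorrelate_profile(
                    simulate_mps_profile(noise_frac=0.3, seed=int(rng.integers(1 << 30))), 600
                )
                for _ in range(n)
            ]
            return average_autocorr(curves)[1].mean()
        assert sem_of(32) < sem_of(8) / 1.5  # ~ 1/sqrt(n)

    def test_grid_mismatch(self):
        a = self._curve(np.ones(5))
        b = AutocorrCurve(lags_nm=np.arange(5) * 20.0, values=np.ones(5))
        with pytest.raises(InputError):
            average_autocorr([a, b])


class TestEstimatePeriod:
    def test_cosine_period_on_grid(self):
        x = np.arange(600)
        p = IntensityProfile(np.cos(2 * np.pi * x * 30.0 / 190.0), px_nm=30.0)
        c = autocorrelate_profile(p, max_lag_nm=600)
        assert estimate_period(c) in (180.0, 210.0)

    def test_white_noise_returns_missing(self):
        misses = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            p = IntensityProfile(rng.standard_normal(333), px_nm=30.0)
            misses += estimate_period(autocorrelate_profile(p, 600)) is None
        assert misses >= 95

    def test_dominant_component_wins(self):
        """Two superimposed periodicities: the estimator returns the dominant
        (high-amplitude) short period, which is also the global
        autocorrelation maximum beyond lag zero."""
        x = np.arange(1000)
        v = np.cos(2 * np.pi * x / 6.0) + 0.25 * np.cos(2 * np.pi * x / 17.0)
        c = autocorrelate_profile(IntensityProfile(v, px_nm=30.0), max_lag_nm=900)
        period = estimate_period(c)
        assert period == pytest.approx(6 * 30.0)

    def test_lattice_recovery_across_spacings(self):
        """Simulated lattices with spacings 150-250 nm are recovered within
        one 30 nm pixel in >= 95% of noisy replicates."""
        hits = trials = 0
        for spacing in (150, 170, 190, 210, 230, 250):
            for seed in range(20):
                p = simulate_mps_profile(spacing_nm=spacing, px_nm=30, length_um=12,
                                         noise_frac=0.1, seed=seed)
                period = estimate_period(autocorrelate_profile(p, 2 * spacing + 120))
                trials += 1
                hits += period is not None and abs(period - spacing) <= 30.0
        assert hits / trials >= 0.95


class TestPatchDetection:
    def test_flat_image_no_patches(self):
        img = np.zeros((30, 60))
        assert detect_patches(img, None) == []

    def test_two_blobs_found_at_truth(self):
        img, truth = simulate_ais_image(n_patches=2, noise_sigma=0.0, seed=1)
        patches = detect_patches(img, None)
        assert len(patches) == 2
        got = sorted(p.centroid for p in patches)
        want = sorted(t["centroid"] for t in truth)
        for g, w in zip(got, want):
            assert abs(g[0] - w[0]) <= 1.0 and abs(g[1] - w[1]) <= 1.0

    def test_count_stable_over_pa_thre(self):
        img, _ = simulate_ais_image(n_patches=2, noise_sigma=0.0, seed=2)
        for pa in np.arange(0.3, 0.95, 0.1):
            assert len(detect_patches(img, None, PatchDetectParams(pa_thre=float(pa)))) == 2

    def test_area_matches_bruteforce_pixel_count(self):
        from scipy.ndimage import gaussian_filter

        img, _ = simulate_ais_image(n_patches=2, noise_sigma=0.0, seed=3)
        params = PatchDetectParams(pa_thre=0.5, area_thre=0.1, smoothing_sigma_px=1.0)
        patches = detect_patches(img, None, params)
        sm = gaussian_filter(img, 1.0)
        bg = np.percentile(img, 10.0)
        thr = bg + 0.5 * (sm.max() - bg)
        assert sum(p.area_px for p in patches) == int(np.sum(sm >= thr))

    def test_lower_threshold_never_shrinks_area(self):
        img, _ = simulate_ais_image(n_patches=3, noise_sigma=5.0, seed=4)
        areas = []
        for pa in (0.9, 0.7, 0.5, 0.3):
            pp = detect_patches(img, None, PatchDetectParams(pa_thre=pa, area_thre=0.01))
            areas.append(sum(p.area_px for p in pp))
        assert areas == sorted(areas)

    def test_determinism(self):
        img, _ = simulate_ais_image(n_patches=4, noise_sigma=10.0, seed=5)
        a = detect_patches(img, None)
        b = detect_patches(img, None)
        assert [(p.centroid, p.area_px) for p in a] == [(p.centroid, p.area_px) for p in b]

    def test_empty_roi_rejected(self):
        with pytest.raises(InputError):
            detect_patches(np.ones((10, 10)), np.zeros((10, 10), bool))


class TestPatchStats:
    def test_no_patches(self):
        area, density = patch_stats([], 12.0)
        assert np.isnan(area) and density == 0.0

    def test_density(self):
        img, _ = simulate_ais_image(n_patches=12, image_shape=(48, 400), seed=6)
        patches = detect_patches(img, None)
        _, density = patch_stats(patches, 15.0)
        assert density == pytest.approx(8.0)


class TestAisLength:
    def test_rectangular_profile(self):
        p = simulate_ais_marker_profile(27.5, px_um=0.09, edge_sigma_um=0.0, noise_frac=0.0)
        ext = measure_ais_length(p, smoothing_um=0.0)
        assert ext.detected
        assert ext.length_um == pytest.approx(27.5, abs=0.09)

    def test_erf_edges_match_analytic_crossing(self):
        L, sigma, px = 25.0, 0.8, 0.05
        p = simulate_ais_marker_profile(L, px_um=px, edge_sigma_um=sigma, noise_frac=0.0)
        ext = measure_ais_length(p, smoothing_um=0.0, threshold_fraction=0.33)
        # analytic: crossings of 0.33 * plateau on the erf-edged profile
        pad = max(5.0, 0.25 * L)
        a, b = pad, pad + L
        s = sigma * np.sqrt(2.0)
        f = lambda x: 0.5 * (erf((x - a) / s) - erf((x - b) / s)) - 0.33
        left = brentq(f, a - 4 * sigma, (a + b) / 2)
        right = brentq(f, (a + b) / 2, b + 4 * sigma)
        assert ext.length_um == pytest.approx(right - left, abs=2 * px)

    def test_all_zero_profile_flagged(self):
        p = IntensityProfile(np.zeros(200), px_nm=90.0)
        ext = measure_ais_length(p)
        assert not ext.detected and ext.length_um == 0.0

    def test_scale_invariance(self):
        p = simulate_ais_marker_profile(20.0, edge_sigma_um=0.5, noise_frac=0.05, seed=7)
        e1 = measure_ais_length(p)
        p2 = IntensityProfile(p.values * 37.5, px_nm=p.px_nm)
        e2 = measure_ais_length(p2)
        assert e1.length_um == pytest.approx(e2.length_um)
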