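import numpy as np
import pandas as pd
import pytest

from sasbx.twinpeaks import (binary_response_fit, bootstrap_curves,
                             detect_twin_peaks, fit_polynomial,
                             geneset_permutation, peak_locations,
                             permutation_test, quadratic_small_delta,
                             select_degree, spline_curve, TwinPeaksRegressor)


def _quartic_profile(x, scale=1.0):
    """Twin-peaks profile x²(1 - x²) scaled; peaks at ±1/√2."""
    return scale * x**2 * (1 - x**2)


class TestFitPolynomial:
    def test_exact_quartic_interpolation(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = -x**4 + 0.5 * x**2
        fit = fit_polynomial(x, y, 4)
        assert np.allclose(fit.coefficients, [0, 0, 0.5, 0, -1], atol=1e-8)
        assert fit.is_twin_peaks is True

    def test_constant_response_null(self, rng):
        x = rng.uniform(-1, 1, 100)
        fit = fit_polynomial(x, np.full(100, 3.0), 4)
        assert fit.p_anova > 0.9
        assert np.allclose(fit.coefficients[1:], 0, atol=1e-8)

    def test_noisy_quadratic_coefficient_recovered(self, rng):
        x = rng.uniform(-1, 1, 500)
        y = x**2 + rng.normal(0, 0.01, 500)
        fit = fit_polynomial(x, y, 2)
        assert fit.coefficients[2] == pytest.approx(1.0, abs=0.02)

    def test_too_few_distinct_deltas(self):
        with pytest.raises(ValueError):
            fit_polynomial([0, 0.5, 1], [1, 2, 3], 4)

    def test_fast_path_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(-1, 1, 300)
        y = _quartic_profile(x) + rng.normal(0, 0.05, 300)
        fit = fit_polynomial(x, y, 4)
        V = np.vander(x, 5, increasing=True)
        res = sm.OLS(y, V).fit()
        assert np.allclose(fit.coefficients, res.params, atol=1e-10)
        assert fit.p_anova == pytest.approx(res.f_pvalue, rel=1e-6, abs=1e-12)


class TestDetectTwinPeaks:
    def test_canonical_twin_peaks(self, rng):
        x = rng.uniform(-1, 1, 300)
        fit = fit_polynomial(x, -x**4 + 0.5 * x**2, 4)
        assert detect_twin_peaks(fit) is True
        maxima, minima = peak_locations(fit.coefficients)
        assert maxima == pytest.approx([-0.5, 0.5], abs=1e-6)
        assert minima == pytest.approx([0.0], abs=1e-6)

    def test_positive_leading_coefficient_fails(self, rng):
        x = rng.uniform(-1, 1, 300)
        fit = fit_polynomial(x, x**4 - 0.5 * x**2, 4)
        assert detect_twin_peaks(fit) is False

    def test_triple_root_counts_once(self, rng):
        """y = -x⁴: the derivative root at 0 has multiplicity 3 but is one
        distinct stationary point, so no twin peaks."""
        x = rng.uniform(-1, 1, 300)
        fit = fit_polynomial(x, -x**4, 4)
        assert fit.derivative_real_roots_in_range == 1
        assert detect_twin_peaks(fit) is False

    def test_wrong_degree_rejected(self, rng):
        x = rng.uniform(-1, 1, 100)
        fit = fit_polynomial(x, x**2, 2)
        with pytest.raises(ValueError):
            detect_twin_peaks(fit)


class TestPeakLocations:
    def test_quadratic_minimum_only(self):
        maxima, minima = peak_locations([0.0, 0.0, 1.0])
        assert len(maxima) == 0
        assert minima == pytest.approx([0.0])

    def test_peaks_outside_interval_excluded(self):
        # y = -x⁴ + 50x²: maxima at ±5, outside [-1, 1]
        maxima, _ = peak_locations([0.0, 0.0, 50.0, 0.0, -1.0])
        assert len(maxima) == 0

    def test_mirror_invariance(self, rng):
        """Δ -> -Δ negates locations and preserves classification."""
        coef = rng.normal(0, 1, 5)
        mirrored = coef * np.array([1, -1, 1, -1, 1])
        max1, min1 = peak_locations(coef)
        max2, min2 = peak_locations(mirrored)
        assert np.allclose(np.sort(-max2), max1, atol=1e-8)
        assert np.allclose(np.sort(-min2), min1, atol=1e-8)


class TestSelectDegree:
    def test_quartic_signal_selects_four(self, rng):
        x = rng.uniform(-1, 1, 2000)
        y = _quartic_profile(x) + rng.normal(0, 0.02, 2000)
        degree, table = select_degree(x, y)
        assert degree == 4
        assert {"degree", "aic", "lrt_p_vs_lower"} <= set(table.columns)

    def test_quadratic_signal_selects_two(self, rng):
        x = rng.uniform(-0.5, 0.5, 2000)
        y = 0.5 * x**2 + rng.normal(0, 0.01, 2000)
        degree, _ = select_degree(x, y)
        assert degree == 2

    def test_pure_noise_selects_low_degree(self, rng):
        x = rng.uniform(-1, 1, 500)
        y = rng.normal(0, 1, 500)
        degree, _ = select_degree(x, y)
        assert degree <= 1


class TestPermutation:
    def test_strong_signal_significant(self, rng):
        """With a clear twin-peaks signal the observed fit shows the
        pattern and the permutation null rate stays below 5% (the p-value
        of this test is the chance rate of the composite pattern, a few
        percent, regardless of how strong the observed signal is)."""
        x = rng.uniform(-1, 1, 2000)
        peak_height = _quartic_profile(1 / np.sqrt(2))
        y = _quartic_profile(x) + rng.normal(0, 0.25 * peak_height, 2000)
        assert fit_polynomial(x, y, 4).is_twin_peaks
        res = permutation_test(x, y, n_perm=1000, seed=5)
        assert res.p_value < 0.05
        assert res.p_value == (res.pattern_count + 1) / (res.n_replicates + 1)

    def test_null_calibration(self, rng):
        """On Δ-independent responses the *observed* quartic rarely shows
        the pattern (that is what detection conditions on), and the
        permutation pattern rate is the stable composite null rate: a few
        percent, consistent between few and many permutations."""
        observed_hits = 0
        for _ in range(10):
            x = rng.uniform(-1, 1, 2000)
            y = rng.normal(0, 1, 2000)
            if fit_polynomial(x, y, 4).is_twin_peaks:
                observed_hits += 1
        assert observed_hits <= 1

        x = rng.uniform(-1, 1, 2000)
        y = rng.normal(0, 1, 2000)
        small = permutation_test(x, y, n_perm=500, seed=1)
        big = permutation_test(x, y, n_perm=5000, seed=2)
        rate_small = small.pattern_count / small.n_replicates
        rate_big = big.pattern_count / big.n_replicates
        se = np.sqrt(rate_big * (1 - rate_big) * (1 / 500 + 1 / 5000))
        assert abs(rate_small - rate_big) < 2.5 * se + 1e-9
        assert rate_big < 0.05

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test([0.1, 0.2], [1, 2], n_perm=0, seed=0)


class TestBootstrap:
    def test_zero_noise_degenerate_cis(self, rng):
        x = rng.uniform(-1, 1, 400)
        y = -x**4 + 0.5 * x**2
        genes = np.repeat([f"g{i}" for i in range(100)], 4)
        res = bootstrap_curves(x, y, genes, n_boot=100, seed=3)
        ci = res.peak_location_ci
        assert ci["left_peak"][1] - ci["left_peak"][0] < 1e-6
        assert res.pattern_count == res.n_replicates

    def test_peak_cis_cover_truth(self, rng):
        x = rng.uniform(-1, 1, 3000)
        peak_height = _quartic_profile(1 / np.sqrt(2))
        y = _quartic_profile(x) + rng.normal(0, 0.2 * peak_height, 3000)
        genes = np.repeat([f"g{i}" for i in range(600)], 5)
        res = bootstrap_curves(x, y, genes, n_boot=300, seed=4)
        ci = res.peak_location_ci
        assert ci["left_peak"][0] <= -1 / np.sqrt(2) <= ci["left_peak"][1]
        assert ci["right_peak"][0] <= 1 / np.sqrt(2) <= ci["right_peak"][1]
        assert res.curve_density["density"].shape[0] == 64

    def test_rank_deficient_replicates_skipped(self, rng):
        # 4 distinct genes, each with one distinct delta: many bootstrap
        # draws collapse to < 5 distinct abscissae
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = rng.normal(0, 1, 4)
        genes = np.array(["a", "b", "c", "d"])
        res = bootstrap_curves(x, y, genes, n_boot=200, seed=6)
        assert res.n_failed > 0
        assert res.n_replicates + res.n_failed == 200


class TestQuadraticSmallDelta:
    def test_model_curvature_recovered(self, rng):
        """Synthetic data from the small-bias prediction with constant A:
        the quadratic coefficient estimates 4·mean(pq)·A."""
        n = 4000
        d = rng.uniform(-0.5, 0.5, n)
        p = rng.uniform(0.1, 0.5, n)
        A = 0.05
        y = 4 * p * (1 - p) * A * d**2 + rng.normal(0, 0.002, n)
        out = quadratic_small_delta(d, y, window=(-0.52, 0.72))
        expected = 4 * np.mean(p * (1 - p)) * A
        assert abs(out["quadratic_coefficient"] - expected) < 3 * out["se"]
        assert out["p_value"] < 1e-6

    def test_flat_response_coefficient_zero(self, rng):
        d = rng.uniform(-1, 1, 1000)
        y = rng.normal(0, 0.01, 1000)
        out = quadratic_small_delta(d, y)
        assert abs(out["quadratic_coefficient"]) < 3 * out["se"] + 1e-9

    def test_degenerate_window(self, rng):
        with pytest.raises(ValueError):
            quadratic_small_delta(rng.uniform(-1, 1, 100),
                                  rng.normal(0, 1, 100), window=(0.1, 0.1))


class TestBinaryResponse:
    def test_twin_peaks_probability_profile_detected(self, rng):
        n = 5000
        d = rng.uniform(-1, 1, n)
        prob = 0.4 * 4 * d**2 * (1 - d**2)
        y = rng.binomial(1, prob)
        res = binary_response_fit(d, y)
        assert res.is_twin_peaks is True
        assert res.binned_fit.coefficients[4] < 0

    def test_constant_probability_not_detected(self, rng):
        hits = 0
        for _ in range(5):
            d = rng.uniform(-1, 1, 3000)
            y = rng.binomial(1, 0.1, 3000)
            if binary_response_fit(d, y).is_twin_peaks:
                hits += 1
        assert hits <= 1

    def test_constant_response_rejected(self, rng):
        d = rng.uniform(-1, 1, 100)
        with pytest.raises(ValueError):
            binary_response_fit(d, np.zeros(100))
        with pytest.raises(ValueError):
            binary_response_fit(d, np.full(100, 0.5))


class TestGenesetPermutation:
    def test_top_subset_extreme_p(self):
        values = pd.Series(np.arange(100, dtype=float),
                           index=[f"g{i}" for i in range(100)])
        top = [f"g{i}" for i in range(95, 100)]
        p = geneset_permutation(values, top, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_random_subset_non_significant(self, rng):
        values = pd.Series(rng.normal(0, 1, 200),
                           index=[f"g{i}" for i in range(200)])
        ps = [geneset_permutation(values, [f"g{i}" for i in rng.choice(200, 20, replace=False)],
                                  n_perm=199, seed=s) for s in range(10)]
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_whole_table_and_missing_rejected(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            geneset_permutation(values, ["a", "b"], 10, 0)
        with pytest.raises(KeyError):
            geneset_permutation(values, ["zzz"], 10, 0)


class TestRegressorAPI:
    def test_sklearn_contract_and_auto_degree(self, rng):
        x = rng.uniform(-1, 1, 2000)
        y = _quartic_profile(x) + rng.normal(0, 0.02, 2000)
        reg = TwinPeaksRegressor(degree="auto")
        assert reg.get_params()["max_degree"] == 6
        reg.fit(x, y)
        assert reg.degree_ == 4
        assert reg.is_twin_peaks_
        assert reg.peaks_ == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)], abs=0.05)
        pred = reg.predict(np.array([[0.0]]))
        assert pred.shape == (1,)

    def test_predict_matches_polynomial(self, rng):
        x = rng.uniform(-1, 1, 100)
        y = 1 + 2 * x + 3 * x**2
        reg = TwinPeaksRegressor(degree=2).fit(x, y)
        assert reg.predict(np.array([0.5])) == pytest.approx(1 + 1 + 0.75, abs=1e-8)


def test_spline_alternative_tracks_profile(rng):
    x = rng.uniform(-1, 1, 4000)
    y = _quartic_profile(x) + rng.normal(0, 0.02, 4000)
    grid, vals = spline_curve(x, y)
    # spline should peak near ±1/√2 and dip near 0
    mid = vals[np.argmin(np.abs(grid))]
    peak = vals[np.argmin(np.abs(grid - 1 / np.sqrt(2)))]
    assert peak > mid
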