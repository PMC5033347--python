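import numpy as np
import pytest

from sasbx.model import (SingularSensitivityError, additive_effect,
                         adult_frequency, delta_from_D, equilibrium_ratio,
                         exact_adult_frequency, expression_to_effects,
                         fst_from_effects, multi_locus_load, predicted_fst,
                         sa_load, sa_load_closed_form, sa_potential)


class TestAdditiveEffect:
    def test_intermediate_dominance_halves_S(self):
        for p in (0.1, 0.5, 0.9):
            assert additive_effect(p, 0.1, 0.5) == pytest.approx(0.05)

    def test_no_selection(self):
        assert additive_effect(0.3, 0.0, 0.2) == 0.0

    def test_hand_arithmetic(self):
        assert additive_effect(0.3, 0.1, 0.2) == pytest.approx(0.038)


class TestAdultFrequency:
    def test_neutral_identity(self):
        assert adult_frequency(0.5, 0.0) == 0.5
        assert exact_adult_frequency(0.5, 0.0, 0.7) == 0.5

    def test_first_order_shift(self):
        assert adult_frequency(0.5, 0.1) == pytest.approx(0.525)

    def test_exact_oracle_hand_value(self):
        assert exact_adult_frequency(0.5, 0.1, 0.5) == pytest.approx(0.5375 / 1.05)

    def test_fixation_invariant(self):
        assert exact_adult_frequency(1.0, 0.3, 0.2) == pytest.approx(1.0)
        assert exact_adult_frequency(0.0, 0.3, 0.2) == pytest.approx(0.0)

    def test_first_order_accuracy_sweep(self):
        """|approx - exact| <= C·s² over |S| <= 0.2 (first-order accuracy)."""
        ps = np.linspace(0.05, 0.95, 19)
        Ss = np.linspace(-0.2, 0.2, 21)
        hs = np.linspace(0.0, 1.0, 5)
        C = 2.0
        for h in hs:
            for S in Ss:
                s = additive_effect(ps, S, h)
                approx = ps + ps * (1 - ps) * s
                exact = exact_adult_frequency(ps, S, h)
                assert np.all(np.abs(approx - exact)
                              <= C * np.maximum(np.abs(s), abs(S)) ** 2 + 1e-15)

    def test_clipping_warns(self):
        with pytest.warns(RuntimeWarning):
            out = adult_frequency(0.9, 5.0)
        assert out == 1.0


class TestExpressionLink:
    def test_no_expression_no_selection(self):
        s_m, s_f = expression_to_effects(0.0, 0.0, 0.01, -0.01)
        assert s_m == 0.0 and s_f == 0.0

    def test_log_scaling(self):
        s_m, _ = expression_to_effects(np.e**2 - 1, 1.0, 0.01, 0.0)
        assert s_m == pytest.approx(0.02)

    def test_sa_potential_hand_value(self):
        assert sa_potential(0.2, -0.1) == pytest.approx(0.04)
        assert sa_potential(0.3, 0.3) == pytest.approx((0.3 / 2) ** 2)

    def test_singular_sensitivities_raise(self):
        with pytest.raises(SingularSensitivityError):
            sa_potential(0.1, -0.1)
        with pytest.raises(SingularSensitivityError):
            equilibrium_ratio(0.1, -0.1)

    def test_equilibrium_ratio_values(self):
        assert equilibrium_ratio(1.0, -1 / 3) == pytest.approx(-2.0)
        assert equilibrium_ratio(0.4, 0.4) == 0.0


class TestFstPrediction:
    def test_concordant_equal_selection_no_divergence(self):
        assert fst_from_effects(0.4, 0.1, 0.1) == 0.0

    def test_hand_value_and_quadratic_scaling(self):
        base = fst_from_effects(0.5, 0.1, -0.1)
        assert base == pytest.approx(0.0025)
        assert fst_from_effects(0.5, 0.2, -0.2) == pytest.approx(4 * base)

    def test_unbiased_expression_zero_divergence(self):
        assert predicted_fst(0.3, 0.05, 0.0) == 0.0

    def test_predicted_fst_hand_value(self):
        assert predicted_fst(0.5, 0.01, 0.5) == pytest.approx(0.0025)

    def test_quadratic_in_delta(self):
        assert predicted_fst(0.3, 0.02, 0.6) == pytest.approx(4 * predicted_fst(0.3, 0.02, 0.3))

    def test_delta_from_D(self):
        assert delta_from_D(0.0) == 0.0
        assert delta_from_D(-0.4) == -delta_from_D(0.4)
        # large-abundance limit: Δ = 0.1 vs ½ln(m/f) = 0.1003
        D = np.log(110 / 90)
        assert delta_from_D(D) == pytest.approx(0.1, abs=1e-3)


def test_eq5_eq14_equilibrium_identity(rng):
    """pq·s_m² = 4pq·A·(D/2)² exactly when a_m·M = -a_f·F (equilibrium)."""
    for _ in range(10_000):
        a_m = rng.uniform(-0.5, 0.5)
        a_f = rng.uniform(-0.5, 0.5)
        if abs(a_m + a_f) < 1e-3 or a_m == 0 or a_f == 0:
            continue
        M = rng.uniform(0.0, 5.0)
        F = -a_m * M / a_f  # equilibrium s_m = -s_f
        if F < 0:
            continue
        p = rng.uniform(0.01, 0.99)
        pq = p * (1 - p)
        s_m = a_m * M
        D = M - F
        A = sa_potential(a_m, a_f)
        assert pq * s_m**2 == pytest.approx(4 * pq * A * (D / 2) ** 2, rel=1e-9, abs=1e-300)


def test_one_generation_stationarity(rng):
    """With exactly antagonistic effects the zygote frequency is stationary
    to first order: |p_next - p| <= C·s² under exact selection."""
    for _ in range(200):
        p = rng.uniform(0.05, 0.95)
        h_m = rng.uniform(0.0, 1.0)
        h_f = rng.uniform(0.0, 1.0)
        S_m = rng.uniform(-0.2, 0.2)
        denom = p + (1 - 2 * p) * h_f
        if abs(denom) < 0.05:
            continue
        # equilibrium condition s_f = -s_m fixes S_f (opposite-sign selection)
        S_f = -(p + (1 - 2 * p) * h_m) / denom * S_m
        p_next = 0.5 * (exact_adult_frequency(p, S_m, h_m)
                        + exact_adult_frequency(p, S_f, h_f))
        s = additive_effect(p, S_m, h_m)
        assert abs(p_next - p) <= 2.0 * max(abs(s), abs(S_m), abs(S_f)) ** 2 + 1e-15


class TestLoad:
    def test_additive_case_equals_s(self):
        for p in (0.1, 0.4, 0.9):
            res = sa_load(p, 0.04, 0.5, 0.5)
            assert res.L_SA == pytest.approx(0.02)

    def test_hand_arithmetic_mortalities(self):
        res = sa_load(0.3, 0.1, h_m=0.2, h_f=0.8)
        assert res.mu_m == pytest.approx(0.0826)
        assert res.mu_f == pytest.approx(0.02611, abs=1e-5)
        assert res.L_SA == pytest.approx(0.674 / 1.24 * 0.1, rel=1e-6)

    def test_no_selection_no_load(self):
        res = sa_load(0.3, 0.0, 0.2, 0.8)
        assert res.mu_m == res.mu_f == res.L_SA == 0.0

    def test_mortality_path_matches_closed_form(self, rng):
        """Averaged-mortality path equals the closed form to 1e-12."""
        for _ in range(2000):
            p = rng.uniform(0.02, 0.98)
            h_m = rng.uniform(0, 1)
            h_f = rng.uniform(0, 1)
            S_m = rng.uniform(0, 0.2)
            if abs(p + (1 - 2 * p) * h_f) < 1e-3:
                continue
            assert sa_load(p, S_m, h_m, h_f).L_SA == pytest.approx(
                sa_load_closed_form(p, S_m, h_m, h_f), abs=1e-12)

    def test_load_nonnegative_iff_selection(self, rng):
        for _ in range(500):
            p = rng.uniform(0.05, 0.95)
            S_m = rng.uniform(0, 0.2)
            res = sa_load(p, S_m, rng.uniform(0, 1), rng.uniform(0.1, 0.9))
            assert res.L_SA >= 0
            assert (res.L_SA == 0) == (S_m == 0)

    def test_singular_dominance_denominator(self):
        with pytest.raises(ZeroDivisionError):
            sa_load(0.0, 0.1, h_m=0.5, h_f=0.0)


class TestMultiLocusLoad:
    def test_hundred_loci_63_percent(self):
        assert multi_locus_load([0.01] * 100) == pytest.approx(1 - 0.99**100)
        assert round(multi_locus_load([0.01] * 100), 2) == 0.63

    def test_single_and_two_loci(self):
        assert multi_locus_load([0.02]) == pytest.approx(0.02)
        assert multi_locus_load([0.5, 0.5]) == pytest.approx(0.75)

    def test_invalid_load_rejected(self):
        with pytest.raises(ValueError):
            multi_locus_load([0.5, 1.0])
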