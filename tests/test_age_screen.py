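"""Variability filter, trajectory selection, F-test, BH, Spearman gate."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from methylshift.age_screen import (ScreenConfig, age_association_test,
                                    bh_adjust, coefficient_of_variation,
                                    fit_best_polynomial, read_models,
                                    screen_age_cpgs, spearman_gate,
                                    variability_filter, write_models)
from methylshift.io import BetaMatrix
from methylshift.preprocess import preprocess

from conftest import cohort_and_matrix, make_linear_truth


def _bm(arr, cpgs=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    cpgs = cpgs or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=cpgs, columns=samples))


class TestCoefficientOfVariation:
    def test_constant_row_zero(self):
        cv = coefficient_of_variation(_bm([[0.5, 0.5, 0.5]]))
        assert cv.iloc[0] == 0.0

    def test_hand_computed(self):
        # row (0.2, 0.4): mean 0.3, sample sd sqrt(0.02) ~ 0.141421
        cv = coefficient_of_variation(_bm([[0.2, 0.4]]))
        assert cv.iloc[0] == pytest.approx(np.sqrt(0.02) / 0.3, abs=1e-9)

    def test_scale_invariance(self, rng):
        row = rng.uniform(0.1, 0.5, size=10)
        cv1 = coefficient_of_variation(_bm([row])).iloc[0]
        cv2 = coefficient_of_variation(_bm([row * 1.7])).iloc[0]
        assert cv1 == pytest.approx(cv2, rel=1e-12)


class TestVariabilityFilter:
    def test_direct_cutoff(self):
        cv = pd.Series([0.1, 0.5, 0.9], index=["a", "b", "c"])
        assert variability_filter(cv, 0.5) == ["b", "c"]

    def test_zero_cutoff_retains_all(self):
        cv = pd.Series([0.0, 0.2], index=["a", "b"])
        assert variability_filter(cv, 0.0) == ["a", "b"]

    def test_all_below_warns_empty(self):
        cv = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.warns(UserWarning, match="variability"):
            assert variability_filter(cv, 0.5) == []

    def test_iqr_mode_uses_quartile_fence(self, rng):
        cv = pd.Series(rng.uniform(0.1, 1.0, 200))
        q1, q3 = cv.quantile([0.25, 0.75])
        kept = variability_filter(cv, 0.5, mode="iqr")
        fence = q1 - 0.5 * (q3 - q1)
        assert len(kept) == int((cv >= fence).sum())


class TestFitBestPolynomial:
    def test_noiseless_linear_selects_linear(self):
        age = np.linspace(20, 80, 40)
        beta = 0.3 + 0.004 * age
        mo = fit_best_polynomial(beta, age)
        assert mo.terms == (0, 1)
        assert mo.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert mo.coefficients[1] == pytest.approx(0.004, abs=1e-10)

    def test_strong_cubic_keeps_cubic_term(self, rng):
        age = rng.uniform(20, 80, 200)
        z = (age - 50) / 30
        beta = 0.5 + 0.3 * z ** 3 + rng.normal(0, 0.01, 200)
        mo = fit_best_polynomial(beta, age)
        assert 3 in mo.terms

    def test_selected_never_beaten_by_enumeration(self, rng):
        """AIC of the selected model matches an independent exhaustive scan."""
        for _ in range(30):
            n = int(rng.integers(12, 40))
            age = rng.uniform(20, 80, n)
            beta = np.clip(rng.normal(0.5, 0.05, n)
                           + rng.normal(0, 0.002) * (age - 50), 0, 1)
            mo = fit_best_polynomial(beta, age)
            best_aic = np.inf
            for powers in [(0,), (0, 1), (0, 2), (0, 3), (0, 1, 2), (0, 1, 3),
                           (0, 2, 3), (0, 1, 2, 3)]:
                X = np.column_stack([age ** p for p in powers])
                rss = float(sm.OLS(beta, X).fit().ssr)
                aic = n * np.log(max(rss, 1e-300) / n) + 2 * len(powers)
                best_aic = min(best_aic, aic)
            sel_aic = mo.n * np.log(max(mo.rss, 1e-300) / mo.n) + 2 * len(mo.terms)
            assert sel_aic <= best_aic + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            fit_best_polynomial(np.full(5, 0.5), np.arange(5, dtype=float))

    def test_few_distinct_ages_truncates_degree(self):
        age = np.array([20.0, 20, 20, 40, 40, 40, 60, 60, 60])
        beta = 0.2 + 0.005 * age
        with pytest.warns(UserWarning, match="distinct ages"):
            mo = fit_best_polynomial(beta, age)
        assert mo.degree <= 2


class TestAgeAssociationTest:
    def test_intercept_only_gives_p_one(self, rng):
        age = rng.uniform(20, 80, 50)
        beta = np.full(50, 0.5) + rng.normal(0, 1e-4, 50)
        mo = fit_best_polynomial(beta, age)
        if mo.terms == (0,):
            assert age_association_test(mo, beta, age) == 1.0

    def test_noiseless_trend_underflows_to_zero(self):
        age = np.linspace(20, 80, 60)
        beta = 0.3 + 0.004 * age
        mo = fit_best_polynomial(beta, age)
        p = age_association_test(mo, beta, age)
        assert p == 0.0 and mo.perfect_fit

    def test_power_at_moderate_effect(self, rng):
        # slope chosen for population R^2 ~ 0.3 at n=300: rejection at
        # BH-corrected 0.01 should be nearly certain
        n, sd = 300, 0.02
        slope = np.sqrt((0.3 / 0.7) * sd ** 2 / 300.0)
        hits = 0
        reps = 50
        for _ in range(reps):
            age = rng.uniform(20, 80, n)
            beta = 0.5 + slope * (age - 50) + rng.normal(0, sd, n)
            mo = fit_best_polynomial(beta, age)
            hits += age_association_test(mo, beta, age) < 0.01 / 10
        assert hits / reps > 0.9


class TestBHAdjust:
    def test_textbook_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(out, [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        out = bh_adjust(np.full(7, 0.04))
        assert np.allclose(out, 0.04, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_matches_step_up_definition_and_permutation_invariant(self, ps):
        p = np.array(ps)
        out = bh_adjust(p)
        # brute-force step-up: sort, p*(m/i), cumulative min from the right
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        assert np.allclose(out, expected, atol=1e-12)
        perm = np.random.default_rng(0).permutation(m)
        assert np.allclose(bh_adjust(p[perm]), out[perm], atol=1e-12)


class TestSpearmanGate:
    def test_monotone_passes_with_rho_one(self):
        age = np.linspace(20, 80, 10)
        ok, rho = spearman_gate(0.1 + 0.01 * age, age)
        assert ok and rho == pytest.approx(1.0)

    def test_negative_rho_uses_absolute_value(self, rng):
        age = np.linspace(20, 80, 200)
        beta = 0.8 - 0.003 * age + rng.normal(0, 0.05, 200)
        ok, rho = spearman_gate(beta, age, threshold=0.2)
        assert rho < 0 and ok

    def test_constant_beta_fails_with_nan(self):
        ok, rho = spearman_gate(np.full(10, 0.4), np.arange(10, dtype=float))
        assert not ok and np.isnan(rho)


class TestScreen:
    def test_planted_recovery_and_attrition(self, default_scenario):
        scen = default_scenario
        clean, _ = preprocess(scen.beta)
        res = screen_age_cpgs(clean, scen.samples, ScreenConfig(cv_cutoff=0.0))
        truth_pos = set(scen.truth.age_related_cpgs)
        surv = set(res.cpg_ids)
        sens = len(surv & truth_pos) / len(truth_pos)
        fdr = len(surv - truth_pos) / max(len(surv), 1)
        assert sens >= 0.9
        assert fdr <= 0.05
        # survivors are nested inside each successive gate's count
        a = res.attrition
        assert a["input"] >= a["cv_filter"] >= a["f_test_r2"] >= a["spearman"]
        assert a["spearman"] == len(res.survivors)

    def test_all_null_matrix_yields_no_survivors(self, rng):
        arr = np.clip(rng.normal(0.5, 0.05, size=(100, 60)), 0, 1)
        m = _bm(arr)
        samples = pd.DataFrame({
            "age": rng.uniform(20, 80, 60),
            "sex": ["male", "female"] * 30,
        }, index=[f"S{j}" for j in range(60)])
        from methylshift.io import SampleTable
        with pytest.warns(UserWarning):
            res = screen_age_cpgs(m, SampleTable(samples),
                                  ScreenConfig(cv_cutoff=0.0))
        assert len(res.survivors) == 0

    def test_u_shape_removed_by_spearman_gate(self, rng):
        # symmetric quadratic: high R^2 but |rho| near zero
        n = 300
        age = rng.uniform(20, 80, n)
        z = (age - 50) / 30
        beta = 0.4 + 0.2 * z ** 2 + rng.normal(0, 0.02, n)
        from methylshift.age_screen import fit_best_polynomial
        mo = fit_best_polynomial(beta, age)
        assert mo.adj_r2 > 0.25
        ok, rho = spearman_gate(beta, age, 0.2)
        assert abs(rho) < 0.2 and not ok

    def test_model_table_round_trip(self, tmp_path):
        truth = make_linear_truth(5, n_per_sex=40, seed=3)
        samples, m = cohort_and_matrix(truth)
        res = screen_age_cpgs(m, samples, ScreenConfig(cv_cutoff=0.0))
        assert res.survivors
        p = tmp_path / "models.tsv"
        write_models(res.survivors, p)
        back = read_models(p)
        assert [b.cpg_id for b in back] == res.cpg_ids
        for orig, b in zip(res.survivors, back):
            assert b.terms == orig.terms
            assert np.allclose(b.coefficients, orig.coefficients, rtol=0)
            assert b.f_p_bh == pytest.approx(orig.f_p_bh, rel=1e-12)
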