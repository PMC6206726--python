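"""Sex-term detection, age-shift estimation and acceleration summary."""

import numpy as np
import pandas as pd
import pytest

from methylshift.age_screen import TrajectoryModel, fit_best_polynomial
from methylshift.sex_shift import (AgeShiftResult, ShiftClass,
                                   ShiftUnidentifiableError,
                                   classify_and_summarize, estimate_age_shift,
                                   sex_term_scan, sex_term_test, shift_scan)

from conftest import cohort_and_matrix, make_linear_truth


def _linear_model(c0=0.3, c1=0.004, cpg="cg0", n=100):
    return TrajectoryModel(cpg_id=cpg, terms=(0, 1),
                           coefficients=np.array([c0, c1]), rss=0.0,
                           adj_r2=1.0, n=n)


class TestSexTerm:
    def test_planted_offset_identified(self, rng):
        n = 200
        age = rng.uniform(20, 80, n)
        sex = np.array(["male", "female"] * (n // 2))
        beta = 0.3 + 0.004 * age + 0.1 * (sex == "female")
        res = sex_term_test(beta, age, sex, (0, 1))
        assert res.sex_coef == pytest.approx(0.1, abs=1e-9)
        assert res.sex_p < 1e-10

    def test_null_p_uniformish(self, rng):
        # no sex effect: p-values should not pile up near zero
        n, reps = 120, 200
        ps = []
        for _ in range(reps):
            age = rng.uniform(20, 80, n)
            sex = np.array(["male", "female"] * (n // 2))
            beta = np.clip(0.3 + 0.004 * age + rng.normal(0, 0.02, n), 0, 1)
            ps.append(sex_term_test(beta, age, sex, (0, 1)).sex_p)
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12

    def test_single_sex_rejected(self):
        age = np.linspace(20, 80, 20)
        with pytest.raises(ValueError, match="both sexes"):
            sex_term_test(0.3 + 0.004 * age, age, np.array(["male"] * 20),
                          (0, 1))

    def test_scan_flags_planted_dimorphism(self):
        truth = make_linear_truth(20, shift=-7.0, n_per_sex=150, seed=21)
        samples, m = cohort_and_matrix(truth)
        models = [fit_best_polynomial(m.values.loc[c].to_numpy(),
                                      samples.ages, c)
                  for c in m.cpg_ids]
        df = sex_term_scan(m, samples, models)
        assert df["dimorphic"].mean() > 0.9


class TestEstimateAgeShift:
    def test_noiseless_recovery_of_minus_seven(self):
        age_m = np.linspace(20, 80, 120)
        age_f = np.linspace(22, 78, 110)
        g = lambda a: 0.3 + 0.004 * a
        model = fit_best_polynomial(g(age_m), age_m, "cg0")
        # women's values follow the men's curve 7 years later in age
        res = estimate_age_shift(g(age_m), age_m, g(age_f - 7), age_f, model)
        assert res.shift_years == pytest.approx(-7.0, abs=1e-3)
        assert res.classification == ShiftClass.ACCELERATED_IN_MEN

    def test_identical_curves_give_no_shift(self):
        age = np.linspace(20, 80, 100)
        g = lambda a: 0.3 + 0.004 * a
        model = fit_best_polynomial(g(age), age, "cg0")
        res = estimate_age_shift(g(age), age, g(age), age, model)
        assert res.shift_years == pytest.approx(0.0, abs=1e-6)
        assert res.shift_p == pytest.approx(1.0)
        assert res.classification == ShiftClass.NO_SHIFT

    def test_antisymmetry_on_noiseless_fixture(self):
        age_a = np.linspace(20, 80, 90)
        age_b = np.linspace(21, 79, 85)
        g = lambda a: 0.25 + 0.005 * a
        model_a = fit_best_polynomial(g(age_a), age_a, "cg0")
        fwd = estimate_age_shift(g(age_a), age_a, g(age_b - 5), age_b, model_a)
        model_b = fit_best_polynomial(g(age_b - 5), age_b, "cg0")
        rev = estimate_age_shift(g(age_b - 5), age_b, g(age_a), age_a, model_b)
        assert fwd.shift_years == pytest.approx(-5.0, abs=1e-3)
        assert rev.shift_years == pytest.approx(+5.0, abs=1e-3)

    def test_rss_inequality(self, rng):
        truth = make_linear_truth(10, shift=-7.0, n_per_sex=80, seed=31)
        samples, m = cohort_and_matrix(truth)
        is_f = (samples.sex == "female").to_numpy()
        age = samples.ages
        for cpg in m.cpg_ids:
            b = m.values.loc[cpg].to_numpy()
            model = fit_best_polynomial(b[~is_f], age[~is_f], cpg)
            res = estimate_age_shift(b[~is_f], age[~is_f], b[is_f],
                                     age[is_f], model)
            assert res.rss_shifted <= res.rss_unshifted + 1e-12

    def test_grid_resolution_invariance_noiseless(self):
        age_m = np.linspace(20, 80, 100)
        age_f = np.linspace(20, 80, 100)
        g = lambda a: 0.3 + 0.004 * a
        model = fit_best_polynomial(g(age_m), age_m, "cg0")
        res = [estimate_age_shift(g(age_m), age_m, g(age_f - 7), age_f,
                                  model, grid_step=step)
               for step in (1.0, 0.5, 0.25)]
        shifts = [r.shift_years for r in res]
        assert max(shifts) - min(shifts) < 1e-3

    def test_flat_model_unidentifiable(self):
        flat = TrajectoryModel(cpg_id="cg0", terms=(0,),
                               coefficients=np.array([0.5]), rss=0.0,
                               adj_r2=0.0, n=50)
        age = np.linspace(20, 80, 50)
        with pytest.raises(ShiftUnidentifiableError):
            estimate_age_shift(np.full(50, 0.5), age, np.full(50, 0.5),
                               age, flat)


class TestSummary:
    def _result(self, shift, p=1e-6):
        cls = (ShiftClass.NO_SHIFT if p >= 0.05 or shift == 0
               else ShiftClass.ACCELERATED_IN_MEN if shift < 0
               else ShiftClass.DELAYED_IN_MEN)
        return AgeShiftResult(cpg_id="x", shift_years=shift, shift_p=p,
                              classification=cls, rss_shifted=1.0,
                              rss_unshifted=2.0)

    def test_all_minus_seven(self):
        s = classify_and_summarize([self._result(-7.0)] * 5)
        assert s.fraction_accelerated == 1.0
        assert s.mean_years_earlier == pytest.approx(7.0)

    def test_mixed_signs(self):
        s = classify_and_summarize([self._result(-7.0), self._result(3.0)])
        assert s.fraction_accelerated == 0.5
        assert s.n_accelerated == 1 and s.n_delayed == 1

    def test_insignificant_excluded(self):
        s = classify_and_summarize([self._result(-7.0),
                                    self._result(-3.0, p=0.5)])
        assert s.n_significant == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_and_summarize([])

    def test_planted_acceleration_fraction_recovered(self, default_scenario):
        scen = default_scenario
        from methylshift.preprocess import preprocess
        from methylshift.age_screen import ScreenConfig, screen_age_cpgs
        clean, _ = preprocess(scen.beta)
        res = screen_age_cpgs(clean, scen.samples, ScreenConfig(cv_cutoff=0.0))
        sex_df = sex_term_scan(clean, scen.samples, res.survivors)
        dim = [mo for mo in res.survivors
               if mo.cpg_id in set(sex_df.loc[sex_df["dimorphic"], "cpg_id"])]
        shifts = shift_scan(clean, scen.samples, dim)
        s = classify_and_summarize(shifts)
        # 40/50 CpGs planted accelerated: estimate within binomial CI of 0.8
        n = s.n_significant
        half = 1.96 * np.sqrt(0.8 * 0.2 / n)
        assert abs(s.fraction_accelerated - 0.8) < half + 0.02
        assert s.mean_years_earlier == pytest.approx(7.0, abs=0.7)
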