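"""Sex-dimorphic CpGs and heterochrony (age-shift) estimation.

Two questions are asked of each age-related CpG:

1. do the sexes differ at all? — a sex term added to the CpG's selected
   polynomial (``sex_term_test``);
2. by how many years is one sex's trajectory displaced along the age axis?
   — the *age shift* ``s`` in the parameterization

       beta_female(a) ~ g(a + s),

   where ``g`` is the shared polynomial trajectory. Under this convention
   ``s < 0`` places the male curve to the left of the female curve: men
   reach a given methylation state at younger ages, the CpG is
   *accelerated in men*. ``s > 0`` means *delayed in men*.

The shift is estimated by nonlinear least squares, profiling the polynomial
coefficients: for each candidate ``s`` the curve is refit jointly on male
samples at their ages and female samples at ``age + s``; a coarse grid scan
over the search bounds is followed by bounded local refinement. Significance
comes from a nested F-test of the shifted model (one extra parameter)
against the common-curve null ``s = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar

from .age_screen import TrajectoryModel, _ols, bh_adjust
from .io import BetaMatrix, SampleTable, align_samples

_TINY = 1e-300


class ShiftClass(str, Enum):
    ACCELERATED_IN_MEN = "accelerated_in_men"
    DELAYED_IN_MEN = "delayed_in_men"
    NO_SHIFT = "no_shift"


class ShiftUnidentifiableError(ValueError):
    """Raised when the trajectory carries no age signal (flat model)."""


@dataclass
class SexTermResult:
    cpg_id: str
    sex_coef: float  # effect of female (vs. male reference) on beta
    sex_p: float
    sex_p_adj: float = np.nan


@dataclass
class AgeShiftResult:
    cpg_id: str
    shift_years: float
    shift_p: float
    classification: ShiftClass
    rss_shifted: float
    rss_unshifted: float
    extrapolated_frac: float = 0.0  # female shifted ages outside male range


# ---------------------------------------------------------------------------
# sex term
# ---------------------------------------------------------------------------

def sex_term_test(beta: np.ndarray, age: np.ndarray, sex: np.ndarray,
                  model_terms: tuple[int, ...], cpg_id: str = "") -> SexTermResult:
    """Add a female indicator to the selected age polynomial and test it.

    ``sex`` holds "male"/"female" per sample; both sexes must be present.
    Returns the female-offset coefficient and its two-sided p-value.
    """
    beta = np.asarray(beta, dtype=float)
    age = np.asarray(age, dtype=float)
    is_f = np.asarray(sex) == "female"
    if is_f.all() or not is_f.any():
        raise ValueError("both sexes must be represented")
    X = np.column_stack([age ** p for p in model_terms] + [is_f.astype(float)])
    fit = sm.OLS(beta, X).fit()
    return SexTermResult(cpg_id=cpg_id,
                         sex_coef=float(fit.params[-1]),
                         sex_p=float(fit.pvalues[-1]))


def sex_term_scan(m: BetaMatrix, samples: SampleTable,
                  models: list[TrajectoryModel],
                  alpha: float = 0.05) -> pd.DataFrame:
    """Sex-term test for each model's CpG, BH-adjusted across the set."""
    m, samples = align_samples(m, samples)
    age = samples.ages
    sex = samples.sex.to_numpy()
    results = []
    for mo in models:
        beta = m.values.loc[mo.cpg_id].to_numpy(dtype=float)
        results.append(sex_term_test(beta, age, sex, mo.terms, mo.cpg_id))
    if results:
        adj = bh_adjust(np.array([r.sex_p for r in results]))
        for r, a in zip(results, adj):
            r.sex_p_adj = float(a)
    df = pd.DataFrame({
        "cpg_id": [r.cpg_id for r in results],
        "sex_coef": [r.sex_coef for r in results],
        "sex_p": [r.sex_p for r in results],
        "sex_p_adj": [r.sex_p_adj for r in results],
    })
    df["dimorphic"] = df["sex_p_adj"] < alpha
    return df


# ---------------------------------------------------------------------------
# age shift
# ---------------------------------------------------------------------------

def _profile_rss(s: float, age_m: np.ndarray, beta_m: np.ndarray,
                 age_f: np.ndarray, beta_f: np.ndarray,
                 powers: tuple[int, ...]) -> float:
    ages = np.concatenate([age_m, age_f + s])
    y = np.concatenate([beta_m, beta_f])
    _, rss = _ols(y, ages, powers)
    return rss


def estimate_age_shift(beta_m: np.ndarray, age_m: np.ndarray,
                       beta_f: np.ndarray, age_f: np.ndarray,
                       male_model: TrajectoryModel,
                       bounds: tuple[float, float] = (-20.0, 20.0),
                       grid_step: float = 0.5,
                       alpha: float = 0.05) -> AgeShiftResult:
    """Estimate the female-vs-male age shift for one CpG.

    The polynomial basis comes from ``male_model`` (the male trajectory is
    the reference object); for each candidate shift the coefficients are
    refit on the pooled data, so the reported F-test compares two honestly
    nested least-squares fits:

        F = (RSS(s=0) - RSS(s_hat)) / (RSS(s_hat) / (n - p - 1)),

    with 1 numerator degree of freedom and ``p`` fitted coefficients.
    Classification: significant negative shift -> accelerated in men,
    significant positive -> delayed in men, otherwise no_shift.
    """
    if male_model.terms == (0,):
        raise ShiftUnidentifiableError(
            f"CpG {male_model.cpg_id!r}: flat trajectory, shift unidentifiable")
    beta_m = np.asarray(beta_m, dtype=float)
    beta_f = np.asarray(beta_f, dtype=float)
    age_m = np.asarray(age_m, dtype=float)
    age_f = np.asarray(age_f, dtype=float)
    lo, hi = bounds
    if not lo < 0 < hi:
        raise ValueError("shift bounds must straddle 0")
    powers = male_model.terms

    def rss_at(s: float) -> float:
        return _profile_rss(s, age_m, beta_m, age_f, beta_f, powers)

    rss0 = rss_at(0.0)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid_rss = np.array([rss_at(s) for s in grid])
    i_best = int(np.argmin(grid_rss))
    s_lo = max(lo, grid[i_best] - grid_step)
    s_hi = min(hi, grid[i_best] + grid_step)
    res = minimize_scalar(rss_at, bounds=(s_lo, s_hi), method="bounded",
                          options={"xatol": 1e-6})
    s_hat, rss_hat = float(res.x), float(res.fun)
    if grid_rss[i_best] < rss_hat:
        s_hat, rss_hat = float(grid[i_best]), float(grid_rss[i_best])
    if rss0 <= rss_hat:  # the extra parameter can never hurt
        s_hat, rss_hat = 0.0, rss0

    n = beta_m.size + beta_f.size
    dof = n - len(powers) - 1
    if dof <= 0:
        raise ValueError("too few samples for the shift F-test")
    if rss_hat <= _TINY:
        shift_p = 1.0 if rss0 - rss_hat <= _TINY else 0.0
    else:
        f = (rss0 - rss_hat) / (rss_hat / dof)
        shift_p = float(stats.f.sf(f, 1, dof))

    if shift_p >= alpha or s_hat == 0.0:
        cls = ShiftClass.NO_SHIFT
    elif s_hat < 0:
        cls = ShiftClass.ACCELERATED_IN_MEN
    else:
        cls = ShiftClass.DELAYED_IN_MEN

    shifted = age_f + s_hat
    extrap = float(np.mean((shifted < age_m.min()) | (shifted > age_m.max())))
    return AgeShiftResult(cpg_id=male_model.cpg_id, shift_years=s_hat,
                          shift_p=shift_p, classification=cls,
                          rss_shifted=rss_hat, rss_unshifted=rss0,
                          extrapolated_frac=extrap)


def shift_scan(m: BetaMatrix, samples: SampleTable,
               models: list[TrajectoryModel],
               bounds: tuple[float, float] = (-20.0, 20.0),
               grid_step: float = 0.5,
               alpha: float = 0.05) -> list[AgeShiftResult]:
    """Estimate the age shift for every model's CpG; flat models are skipped.

    The male trajectory is refit per CpG on male samples only so that its
    selected terms reflect the reference sex, falling back to the pooled
    model's terms for the basis.
    """
    from .age_screen import fit_best_polynomial

    m, samples = align_samples(m, samples)
    is_f = (samples.sex == "female").to_numpy()
    age = samples.ages
    results: list[AgeShiftResult] = []
    for mo in models:
        beta = m.values.loc[mo.cpg_id].to_numpy(dtype=float)
        beta_m, age_m = beta[~is_f], age[~is_f]
        beta_f, age_f = beta[is_f], age[is_f]
        male_model = fit_best_polynomial(beta_m, age_m, cpg_id=mo.cpg_id)
        if male_model.terms == (0,):
            male_model = TrajectoryModel(
                cpg_id=mo.cpg_id, terms=mo.terms,
                coefficients=mo.coefficients, rss=male_model.rss,
                adj_r2=male_model.adj_r2, n=male_model.n)
        if male_model.terms == (0,):
            continue
        results.append(estimate_age_shift(
            beta_m, age_m, beta_f, age_f, male_model,
            bounds=bounds, grid_step=grid_step, alpha=alpha))
    return results


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class ShiftSummary:
    n_total: int
    n_significant: int
    n_accelerated: int
    n_delayed: int
    fraction_accelerated: float  # among significant shifts
    mean_years_earlier: float    # mean |shift| over accelerated CpGs


def classify_and_summarize(results: list[AgeShiftResult],
                           alpha: float = 0.05) -> ShiftSummary:
    """Aggregate shift results: accelerated/delayed counts and mean lead.

    "Years earlier in men" is the mean absolute shift over the CpGs
    classified accelerated at the given alpha.
    """
    if not results:
        raise ValueError("no shift results to summarize")
    sig = [r for r in results if r.shift_p < alpha and r.shift_years != 0]
    acc = [r for r in sig if r.shift_years < 0]
    del_ = [r for r in sig if r.shift_years > 0]
    frac = len(acc) / len(sig) if sig else float("nan")
    mean_earlier = (float(np.mean([abs(r.shift_years) for r in acc]))
                    if acc else float("nan"))
    return ShiftSummary(n_total=len(results), n_significant=len(sig),
                        n_accelerated=len(acc), n_delayed=len(del_),
                        fraction_accelerated=frac,
                        mean_years_earlier=mean_earlier)


def shifts_to_table(results: list[AgeShiftResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "cpg_id": [r.cpg_id for r in results],
        "shift_years": [r.shift_years for r in results],
        "shift_p": [r.shift_p for r in results],
        "classification": [r.classification.value for r in results],
        "rss_shifted": [r.rss_shifted for r in results],
        "rss_unshifted": [r.rss_unshifted for r in results],
    })
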