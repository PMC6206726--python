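"""Screening for age-related CpGs.

A CpG is called age-related when it survives four gates applied in order:

1. a variability prefilter on the coefficient of variation (cv = sd/mean);
2. a polynomial trajectory fit of beta on age (cubic at most), with the
   model chosen by backward elimination under AIC;
3. an F-test of the selected model against the intercept-only null,
   Benjamini-Hochberg corrected across all tested CpGs, together with an
   adjusted-R-squared floor;
4. a Spearman rank-correlation gate on |rho|.

The trajectory model of each survivor (terms, coefficients, fit statistics)
is carried forward to the sex-dimorphism and age-shift stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, SampleTable, align_samples

_TINY = 1e-300


@dataclass
class ScreenConfig:
    """Gate thresholds for the age screen.

    cv_cutoff
        Minimum coefficient of variation retained by the prefilter.
    cv_mode
        ``"cv"`` (default): retain cv >= cv_cutoff directly.
        ``"iqr"``: retain cv above the lower quartile fence of the cv
        distribution, Q1 - cv_cutoff * IQR (an alternate reading of a
        quartile-based cut).
    p_threshold
        BH-adjusted F-test p-value ceiling.
    adj_r2_threshold
        Adjusted R-squared floor for the selected model.
    spearman_abs_threshold
        |Spearman rho| must strictly exceed this.
    """

    cv_cutoff: float = 0.5
    cv_mode: str = "cv"
    p_threshold: float = 0.01
    adj_r2_threshold: float = 0.25
    spearman_abs_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.cv_mode not in ("cv", "iqr"):
            raise ValueError("cv_mode must be 'cv' or 'iqr'")
        if not (0 <= self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in [0, 1]")
        if self.cv_cutoff < 0:
            raise ValueError("cv_cutoff must be >= 0")


@dataclass
class TrajectoryModel:
    """Best-fit polynomial of methylation on age for one CpG.

    ``terms`` lists the included age powers (0 = intercept, always present);
    ``coefficients`` aligns with ``terms`` on the raw-year scale, so the
    fitted curve is sum_i coefficients[i] * age**terms[i].
    """

    cpg_id: str
    terms: tuple[int, ...]
    coefficients: np.ndarray
    rss: float
    adj_r2: float
    n: int
    f_p: float = np.nan
    f_p_bh: float = np.nan
    spearman_rho: float = np.nan
    perfect_fit: bool = False

    def predict(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        out = np.zeros_like(age)
        for p, c in zip(self.terms, self.coefficients):
            out += c * age ** p
        return out

    @property
    def degree(self) -> int:
        return max(self.terms)


# ---------------------------------------------------------------------------
# variability prefilter
# ---------------------------------------------------------------------------

def coefficient_of_variation(m: BetaMatrix) -> pd.Series:
    """Per-CpG coefficient of variation: sample sd (ddof=1) over mean."""
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    means = X.mean(axis=1)
    if (means <= 0).any():
        bad = m.values.index[means <= 0][0]
        raise ValueError(f"CpG {bad!r} has non-positive mean; cv undefined")
    sds = X.std(axis=1, ddof=1)
    return pd.Series(sds / means, index=m.values.index, name="cv")


def variability_filter(cv: pd.Series, cutoff: float = 0.5,
                       mode: str = "cv") -> list[str]:
    """Retain CpG ids whose cv clears the cutoff (see :class:`ScreenConfig`)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if mode == "cv":
        threshold = cutoff
    elif mode == "iqr":
        q1, q3 = cv.quantile([0.25, 0.75])
        threshold = q1 - cutoff * (q3 - q1)
    else:
        raise ValueError("mode must be 'cv' or 'iqr'")
    keep = cv.index[cv.to_numpy() >= threshold]
    if len(keep) == 0:
        warnings.warn("no CpGs pass the variability filter", stacklevel=2)
    return list(keep)


# ---------------------------------------------------------------------------
# polynomial trajectory selection
# ---------------------------------------------------------------------------

def _ols(beta: np.ndarray, age: np.ndarray,
         powers: tuple[int, ...]) -> tuple[np.ndarray, float]:
    """Least-squares fit of beta on the given age powers; returns (coef, rss).

    Columns are norm-scaled before the solve so the raw-year cubic design
    stays well conditioned; coefficients are mapped back to the raw scale.
    """
    X = np.column_stack([age ** p for p in powers])
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    coef_scaled, _, rank, _ = np.linalg.lstsq(X / scale, beta, rcond=None)
    if rank < len(powers):
        raise np.linalg.LinAlgError(
            f"rank-deficient design for powers {powers}")
    coef = coef_scaled / scale
    resid = beta - X @ coef
    return coef, float(resid @ resid)


def _aic(rss: float, n: int, n_params: int, floor: float = _TINY) -> float:
    # rss is floored so that numerically-perfect fits cannot reward extra
    # terms through log-of-roundoff noise; the penalty then decides
    return n * np.log(max(rss, floor) / n) + 2 * n_params


def fit_best_polynomial(beta: np.ndarray, age: np.ndarray,
                        cpg_id: str = "") -> TrajectoryModel:
    """Select the best polynomial of beta on age (degree <= 3) by AIC.

    Starting from the full cubic, terms are eliminated backward; with only
    three removable powers the backward-reachable candidate set (every
    subset of {age, age^2, age^3} plus the intercept) is searched
    exhaustively, so the returned model is the AIC optimum of that set.
    Ties prefer the smaller model. If the ages take fewer than four
    distinct values the candidate degrees are truncated to what remains
    identifiable.
    """
    beta = np.asarray(beta, dtype=float)
    age = np.asarray(age, dtype=float)
    n = beta.size
    if n < 8:
        raise ValueError("need at least 8 samples to fit the trajectory")
    n_distinct = np.unique(age).size
    max_pow = min(3, n_distinct - 1)
    if max_pow < 1:
        raise ValueError("age must take at least 2 distinct values")
    if max_pow < 3:
        warnings.warn(
            f"only {n_distinct} distinct ages; truncating candidate degree "
            f"to {max_pow}", stacklevel=2)

    removable = tuple(range(1, max_pow + 1))
    tss0 = float(((beta - beta.mean()) ** 2).sum())
    floor = max(1e-14 * tss0, _TINY)
    best: tuple[float, int, tuple[int, ...], np.ndarray, float] | None = None
    for size in range(len(removable) + 1):
        for subset in combinations(removable, size):
            powers = (0,) + subset
            coef, rss = _ols(beta, age, powers)
            aic = _aic(rss, n, len(powers), floor)
            key = (aic, len(powers), powers)
            if best is None or key < (best[0], best[1], best[2]):
                best = (aic, len(powers), powers, coef, rss)
    assert best is not None
    _, _, powers, coef, rss = best

    tss = float(((beta - beta.mean()) ** 2).sum())
    k = len(powers)
    if tss <= 0 or n - k <= 0:
        adj_r2 = 0.0
    else:
        adj_r2 = 1.0 - (rss / (n - k)) / (tss / (n - 1))
    return TrajectoryModel(cpg_id=cpg_id, terms=powers,
                           coefficients=np.asarray(coef, dtype=float),
                           rss=rss, adj_r2=adj_r2, n=n)


def age_association_test(model: TrajectoryModel, beta: np.ndarray,
                         age: np.ndarray) -> float:
    """Nested F-test of the selected trajectory against the flat null.

    F = ((RSS0 - RSS1)/ddf) / (RSS1/(n - p1)) with RSS0 the intercept-only
    residual sum of squares. If the selected model *is* the null the p-value
    is 1; a perfect fit (RSS1 = 0) yields p = 0 and sets ``perfect_fit``.
    """
    beta = np.asarray(beta, dtype=float)
    n = beta.size
    if model.terms == (0,):
        model.f_p = 1.0
        return 1.0
    rss0 = float(((beta - beta.mean()) ** 2).sum())
    rss1 = model.rss
    p1 = len(model.terms)
    ddf = p1 - 1
    if rss1 <= max(1e-14 * rss0, _TINY):
        model.perfect_fit = True
        model.f_p = 0.0
        return 0.0
    f = ((rss0 - rss1) / ddf) / (rss1 / (n - p1))
    p = float(stats.f.sf(f, ddf, n - p1))
    model.f_p = p
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_gate(beta: np.ndarray, age: np.ndarray,
                  threshold: float = 0.2) -> tuple[bool, float]:
    """Spearman rank-correlation gate: pass iff |rho| > threshold.

    A constant beta vector leaves rho undefined and fails the gate.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size < 3:
        raise ValueError("need at least 3 samples for the Spearman gate")
    if np.ptp(beta) == 0 or np.ptp(age) == 0:
        return False, float("nan")
    rho = float(stats.spearmanr(beta, age).statistic)
    return bool(abs(rho) > threshold), rho


# ---------------------------------------------------------------------------
# composite screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Survivors of the age screen plus per-gate attrition counts."""

    survivors: list[TrajectoryModel]
    attrition: dict[str, int] = field(default_factory=dict)
    all_models: list[TrajectoryModel] = field(default_factory=list)

    @property
    def cpg_ids(self) -> list[str]:
        return [m.cpg_id for m in self.survivors]

    def table(self) -> pd.DataFrame:
        return models_to_table(self.survivors)


def screen_age_cpgs(m: BetaMatrix, samples: SampleTable,
                    cfg: ScreenConfig | None = None) -> ScreenResult:
    """Run the full age screen; returns survivors with fitted models.

    BH correction is applied across every CpG that reached the F-test,
    i.e. the variability-filter survivors.
    """
    cfg = cfg or ScreenConfig()
    m, samples = align_samples(m, samples)
    age = samples.ages
    cv = coefficient_of_variation(m)
    kept = variability_filter(cv, cfg.cv_cutoff, cfg.cv_mode)
    attrition = {"input": m.shape[0], "cv_filter": len(kept)}

    models: list[TrajectoryModel] = []
    for cpg in kept:
        beta = m.values.loc[cpg].to_numpy(dtype=float)
        model = fit_best_polynomial(beta, age, cpg_id=cpg)
        age_association_test(model, beta, age)
        _, rho = spearman_gate(beta, age, cfg.spearman_abs_threshold)
        model.spearman_rho = rho
        models.append(model)

    if models:
        adj = bh_adjust(np.array([mo.f_p for mo in models]))
        for mo, a in zip(models, adj):
            mo.f_p_bh = float(a)

    after_p = [mo for mo in models
               if mo.f_p_bh < cfg.p_threshold and mo.adj_r2 > cfg.adj_r2_threshold]
    attrition["f_test_r2"] = len(after_p)
    survivors = [mo for mo in after_p
                 if np.isfinite(mo.spearman_rho)
                 and abs(mo.spearman_rho) > cfg.spearman_abs_threshold]
    attrition["spearman"] = len(survivors)
    if not survivors:
        warnings.warn("no CpGs survive the age screen", stacklevel=2)
    return ScreenResult(survivors=survivors, attrition=attrition,
                        all_models=models)


# ---------------------------------------------------------------------------
# model table serialization (used by the CLI to chain stages)
# ---------------------------------------------------------------------------

def models_to_table(models: list[TrajectoryModel]) -> pd.DataFrame:
    rows = []
    for mo in models:
        rows.append({
            "cpg_id": mo.cpg_id,
            "terms": ",".join(str(t) for t in mo.terms),
            "coefficients": ",".join(repr(float(c)) for c in mo.coefficients),
            "rss": mo.rss,
            "adj_r2": mo.adj_r2,
            "n": mo.n,
            "f_p": mo.f_p,
            "f_p_bh": mo.f_p_bh,
            "spearman_rho": mo.spearman_rho,
        })
    cols = ["cpg_id", "terms", "coefficients", "rss", "adj_r2", "n",
            "f_p", "f_p_bh", "spearman_rho"]
    return pd.DataFrame(rows, columns=cols)


def write_models(models: list[TrajectoryModel], path: str | Path) -> None:
    models_to_table(models).to_csv(path, sep="\t", index=False)


def read_models(path: str | Path) -> list[TrajectoryModel]:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str})
    out = []
    for row in df.itertuples(index=False):
        terms = tuple(int(t) for t in str(row.terms).split(","))
        coef = np.array([float(c) for c in str(row.coefficients).split(",")])
        out.append(TrajectoryModel(
            cpg_id=row.cpg_id, terms=terms, coefficients=coef,
            rss=float(row.rss), adj_r2=float(row.adj_r2), n=int(row.n),
            f_p=float(row.f_p), f_p_bh=float(row.f_p_bh),
            spearman_rho=float(row.spearman_rho)))
    return out
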