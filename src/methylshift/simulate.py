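"""Synthetic methylation cohorts with known ground truth.

The generator emulates the structure of a blood HM450-style dataset:
bounded beta values following per-CpG polynomial age trajectories, a
planted per-CpG sex age-shift (the female curve is the shared trajectory
evaluated at ``age + shift``, matching the estimation convention: shift
< 0 means men's curve lies left, i.e. accelerated in men), additive
Gaussian noise on the beta scale clipped to [0, 1], sparse missingness,
and exposure effects directionally aligned or opposed to the age trend.

Everything is a pure function of (parameters, seed); the ground truth is
serializable to JSON and regeneration from a reloaded truth is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (BetaMatrix, CpGAnnotation, GeneSetCollection, SampleTable)

#: default additive noise sd on the beta scale
DEFAULT_NOISE_SD = 0.02

_TRUTH_COLUMNS = ["c0", "c1", "c2", "c3", "shift_years", "is_age_related",
                  "gene", "drinker_effect", "smoker_effect"]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``cpgs`` is indexed by CpG id with polynomial coefficients ``c0..c3``
    (beta units per year^d), the planted sex age shift in years (0 for
    non-dimorphic CpGs), an age-relatedness flag, the assigned gene, and
    signed exposure effects in beta units (0 = no effect).
    """

    cpgs: pd.DataFrame
    n_per_sex: int
    age_lo: float
    age_hi: float
    noise_sd: float
    missing_frac: float
    seed: int

    def __post_init__(self) -> None:
        missing = set(_TRUTH_COLUMNS) - set(self.cpgs.columns)
        if missing:
            raise ValueError(f"truth table lacks columns {sorted(missing)}")

    # -- trajectory evaluation -----------------------------------------
    def trajectory(self, cpg: str, ages: np.ndarray) -> np.ndarray:
        row = self.cpgs.loc[cpg]
        a = np.asarray(ages, dtype=float)
        return (row["c0"] + row["c1"] * a + row["c2"] * a ** 2
                + row["c3"] * a ** 3)

    @property
    def age_related_cpgs(self) -> list[str]:
        return list(self.cpgs.index[self.cpgs["is_age_related"]])

    @property
    def dimorphic_cpgs(self) -> list[str]:
        return list(self.cpgs.index[self.cpgs["shift_years"] != 0])

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {
                "n_per_sex": self.n_per_sex, "age_lo": self.age_lo,
                "age_hi": self.age_hi, "noise_sd": self.noise_sd,
                "missing_frac": self.missing_frac, "seed": self.seed,
            },
            "cpg_ids": list(self.cpgs.index),
            "columns": _TRUTH_COLUMNS,
            "rows": [
                [row[c] if isinstance(row[c], str) else
                 (bool(row[c]) if c == "is_age_related" else float(row[c]))
                 for c in _TRUTH_COLUMNS]
                for _, row in self.cpgs.iterrows()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["rows"], columns=payload["columns"],
                          index=pd.Index(payload["cpg_ids"], name="cpg_id"))
        for c in ("c0", "c1", "c2", "c3", "shift_years",
                  "drinker_effect", "smoker_effect"):
            df[c] = df[c].astype(float)
        df["is_age_related"] = df["is_age_related"].astype(bool)
        return cls(cpgs=df, **payload["params"])


# ---------------------------------------------------------------------------
# cohort and matrix generation
# ---------------------------------------------------------------------------

def generate_cohort(n_per_sex: int, age_lo: float = 20.0, age_hi: float = 80.0,
                    seed: int = 0,
                    exposure_rates: dict[str, float] | None = None
                    ) -> SampleTable:
    """Balanced two-sex cohort with uniform ages and Bernoulli exposures."""
    if n_per_sex < 1:
        raise ValueError("n_per_sex must be >= 1")
    if not age_lo < age_hi:
        raise ValueError("need age_lo < age_hi")
    rng = np.random.default_rng([seed, 1])
    n = 2 * n_per_sex
    ids = [f"S{i:05d}" for i in range(n)]
    ages = rng.uniform(age_lo, age_hi, size=n)
    sex = ["male"] * n_per_sex + ["female"] * n_per_sex
    data = pd.DataFrame({"age": ages, "sex": sex},
                        index=pd.Index(ids, name="sample_id"))
    for name, rate in (exposure_rates or {}).items():
        data[name] = rng.random(n) < rate
    return SampleTable(data)


def generate_beta_matrix(samples: SampleTable,
                         truth: SyntheticTruth) -> BetaMatrix:
    """Evaluate the planted trajectories with noise and exposure effects.

    Male samples take g(age); female samples take g(age + shift). If any
    trajectory leaves [0, 1] before noise over its evaluation range the
    generation fails, naming the CpG; after noise, values are clipped.
    """
    rng = np.random.default_rng([truth.seed, 7])
    ages = samples.ages
    is_f = (samples.sex == "female").to_numpy()
    exposures = {e: samples.data[e].to_numpy(dtype=bool)
                 for e in samples.exposures}
    n_cpg, n_s = len(truth.cpgs), len(samples)
    values = np.empty((n_cpg, n_s))
    for i, cpg in enumerate(truth.cpgs.index):
        shift = float(truth.cpgs.loc[cpg, "shift_years"])
        eval_ages = np.where(is_f, ages + shift, ages)
        clean = truth.trajectory(cpg, eval_ages)
        # bound check over the evaluation range, pre-noise
        lo = min(ages.min(), eval_ages.min())
        hi = max(ages.max(), eval_ages.max())
        grid = truth.trajectory(cpg, np.linspace(lo, hi, 101))
        if grid.min() < 0 or grid.max() > 1:
            raise ValueError(
                f"CpG {cpg!r}: trajectory escapes [0, 1] on ages "
                f"[{lo:.1f}, {hi:.1f}] before noise")
        for name, flags in exposures.items():
            col = f"{name}_effect"
            if col in truth.cpgs.columns:
                clean = clean + float(truth.cpgs.loc[cpg, col]) * flags
        values[i] = clean + rng.normal(0.0, truth.noise_sd, size=n_s)
    np.clip(values, 0.0, 1.0, out=values)
    df = pd.DataFrame(values, index=pd.Index(truth.cpgs.index, name="cpg_id"),
                      columns=samples.sample_ids)
    return BetaMatrix(df)


def inject_missingness(m: BetaMatrix, frac: float, seed: int = 0,
                       heavy_cpgs: list[str] | None = None,
                       heavy_frac: float = 0.10) -> BetaMatrix:
    """Mask cells uniformly at rate ``frac``; optionally give selected CpGs
    a fixed ``heavy_frac`` of missing cells (to exercise the missingness
    filter). Every CpG keeps at least one observed cell."""
    if not 0 <= frac < 1:
        raise ValueError("frac must lie in [0, 1)")
    rng = np.random.default_rng([seed, 11])
    X = m.values.to_numpy(dtype=float, copy=True)
    n_cpg, n_s = X.shape
    if frac > 0:
        mask = rng.random(X.shape) < frac
    else:
        mask = np.zeros(X.shape, dtype=bool)
    index = list(m.values.index)
    for cpg in heavy_cpgs or []:
        i = index.index(cpg)
        n_mask = int(np.ceil(heavy_frac * n_s))
        cols = rng.choice(n_s, size=n_mask, replace=False)
        mask[i] = False
        mask[i, cols] = True
    # keep at least one observed value per CpG
    full_rows = np.where(mask.all(axis=1))[0]
    for i in full_rows:
        mask[i, rng.integers(n_s)] = False
    X[mask] = np.nan
    return BetaMatrix(pd.DataFrame(X, index=m.values.index,
                                   columns=m.values.columns))


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

def _slope_for_r2(r2: float, noise_sd: float, age_lo: float,
                  age_hi: float) -> float:
    """Linear slope giving population R^2 = r2 under uniform ages + noise."""
    age_var = (age_hi - age_lo) ** 2 / 12.0
    return float(np.sqrt((r2 / (1 - r2)) * noise_sd ** 2 / age_var))


@dataclass
class DefaultScenario:
    """The bundled study fixture (see :func:`make_default_scenario`)."""

    beta: BetaMatrix
    samples: SampleTable
    annotation: CpGAnnotation
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def make_default_scenario(seed: int,
                          n_per_sex: int = 150,
                          noise_sd: float = DEFAULT_NOISE_SD,
                          missing_frac: float = 0.02,
                          n_heavy_missing: int = 10,
                          age_lo: float = 20.0,
                          age_hi: float = 80.0) -> DefaultScenario:
    """Standard 500-CpG cohort with planted structure.

    Composition: 300 null CpGs (flat trajectories), 150 age-related
    non-dimorphic CpGs with linear slopes calibrated to a population
    R^2 of 0.4 at the default noise, and 50 sex-dimorphic CpGs with
    steeper slopes (0.004 / yr): 40 planted at shift -7 years
    (accelerated in men) and 10 at +4 (delayed). Each CpG carries one
    gene; dimorphic genes enter a synthetic "CVD" set at 5x the
    background rate. Drinker exposure effects (|0.05| beta units) are
    planted on 48 of the 50 dimorphic CpGs, 36 aligned with the age
    trend and 12 opposed (75% concordant). The first ``n_heavy_missing``
    null CpGs get 10% missing cells to exercise the missingness filter;
    all others miss cells at ``missing_frac``.
    """
    rng = np.random.default_rng([seed, 3])
    n_null, n_age, n_acc, n_del = 300, 150, 40, 10
    n_total = n_null + n_age + n_acc + n_del
    cpg_ids = [f"cg{i:08d}" for i in range(n_total)]
    genes = [f"G{i:04d}" for i in range(n_total)]

    rows = []
    slope_age = _slope_for_r2(0.4, noise_sd, age_lo, age_hi)
    mid_age = (age_lo + age_hi) / 2
    for i in range(n_total):
        c1 = c2 = c3 = 0.0
        shift = 0.0
        age_related = False
        if i < n_null:
            c0 = rng.uniform(0.2, 0.8)
        elif i < n_null + n_age:
            sign = rng.choice([-1.0, 1.0])
            c1 = sign * slope_age
            mid = rng.uniform(0.3, 0.7)
            c0 = mid - c1 * mid_age
            age_related = True
        else:
            sign = rng.choice([-1.0, 1.0])
            c1 = sign * 0.004
            mid = rng.uniform(0.35, 0.65)
            c0 = mid - c1 * mid_age
            shift = -7.0 if i < n_null + n_age + n_acc else 4.0
            age_related = True
        rows.append({"c0": c0, "c1": c1, "c2": c2, "c3": c3,
                     "shift_years": shift, "is_age_related": age_related,
                     "gene": genes[i], "drinker_effect": 0.0,
                     "smoker_effect": 0.0})
    cpgs = pd.DataFrame(rows, index=pd.Index(cpg_ids, name="cpg_id"))

    # drinker effects on 48/50 dimorphic CpGs: 36 aligned, 12 opposed
    dim_ids = cpg_ids[n_null + n_age:]
    perm = rng.permutation(len(dim_ids))
    aligned = [dim_ids[j] for j in perm[:36]]
    opposed = [dim_ids[j] for j in perm[36:48]]
    for cid in aligned:
        cpgs.loc[cid, "drinker_effect"] = 0.05 * np.sign(cpgs.loc[cid, "c1"])
    for cid in opposed:
        cpgs.loc[cid, "drinker_effect"] = -0.05 * np.sign(cpgs.loc[cid, "c1"])

    truth = SyntheticTruth(cpgs=cpgs, n_per_sex=n_per_sex, age_lo=age_lo,
                           age_hi=age_hi, noise_sd=noise_sd,
                           missing_frac=missing_frac, seed=seed)

    samples = generate_cohort(n_per_sex, age_lo, age_hi, seed=seed,
                              exposure_rates={"drinker": 0.30})
    beta = generate_beta_matrix(samples, truth)
    heavy = cpg_ids[:n_heavy_missing]
    beta = inject_missingness(beta, missing_frac, seed=seed, heavy_cpgs=heavy)

    annotation = CpGAnnotation(pd.DataFrame({"cpg_id": cpg_ids, "gene": genes}))
    dim_genes = set(cpgs.loc[dim_ids, "gene"])
    in_cvd = []
    for g in genes:
        rate = 0.5 if g in dim_genes else 0.1
        if rng.random() < rate:
            in_cvd.append(g)
    gene_sets = GeneSetCollection({"CVD": frozenset(in_cvd)})
    return DefaultScenario(beta=beta, samples=samples, annotation=annotation,
                           gene_sets=gene_sets, truth=truth)
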