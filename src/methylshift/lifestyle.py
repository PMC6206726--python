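"""Exposure (drinking / smoking) differential methylation and direction
concordance with the age-related change.

Differential CpGs are called with a two-sample Student's t-test at raw
p < alpha (no multiplicity correction; stated in output). Concordance asks
whether the exposed-vs-unexposed difference points the same way as the
age-related change, whose direction is taken as the sign of the Spearman
rho recorded during the age screen (the trajectory-slope sign at a
reference age is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, SampleTable, align_samples


@dataclass
class ExposureResult:
    cpg_id: str
    mean_exposed: float
    mean_unexposed: float
    delta: float  # exposed - unexposed
    p: float
    differential: bool


def differential_by_exposure(m: BetaMatrix, samples: SampleTable,
                             exposure: str,
                             cpgs: Sequence[str] | None = None,
                             alpha: float = 0.05,
                             welch: bool = False) -> pd.DataFrame:
    """Per-CpG exposed-vs-unexposed t-test; rows flagged at raw p < alpha."""
    if exposure not in samples.exposures:
        raise ValueError(
            f"sample table has no exposure flag {exposure!r}; "
            f"available: {samples.exposures}")
    m, samples = align_samples(m, samples)
    flag = samples.data[exposure].to_numpy(dtype=bool)
    if flag.sum() < 2 or (~flag).sum() < 2:
        raise ValueError("each exposure group needs at least 2 samples")
    if cpgs is None:
        cpgs = m.cpg_ids
    rows = []
    for cpg in cpgs:
        beta = m.values.loc[cpg].to_numpy(dtype=float)
        a, b = beta[flag], beta[~flag]
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        delta = float(a.mean() - b.mean())
        rows.append({"cpg_id": cpg, "mean_exposed": float(a.mean()),
                     "mean_unexposed": float(b.mean()), "delta": delta,
                     "p": p, "differential": p < alpha})
    return pd.DataFrame(rows)


def direction_concordance(results: pd.DataFrame,
                          age_directions: Mapping[str, float] | pd.Series
                          ) -> tuple[float, int, int]:
    """Fraction of differential CpGs whose delta sign matches the age sign.

    ``age_directions`` maps cpg_id to a signed quantity (e.g. Spearman rho
    from the screen); only its sign is used. CpGs with a zero delta or zero
    age direction are excluded and counted.

    Returns (concordant fraction, n compared, n excluded for zero signs).
    """
    diff = results[results["differential"]]
    n_excluded = 0
    agree = 0
    compared = 0
    for row in diff.itertuples(index=False):
        direction = float(age_directions[row.cpg_id])
        if row.delta == 0 or direction == 0 or not np.isfinite(direction):
            n_excluded += 1
            continue
        compared += 1
        if np.sign(row.delta) == np.sign(direction):
            agree += 1
    frac = agree / compared if compared else float("nan")
    return frac, compared, n_excluded
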