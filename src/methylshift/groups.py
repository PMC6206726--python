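"""Age-group analyses: between-sex differences per group and within-sex
comparisons against the youngest (control) group.

Groups are half-open intervals [lo, hi) in years. Significance uses
Student's equal-variance t-test by default (Welch optionally); group tables
carry raw p-values without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, SampleTable, align_samples


@dataclass
class AgeGroupScheme:
    """Ordered, non-overlapping half-open age intervals with labels."""

    intervals: list[tuple[float, float]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.labels):
            raise ValueError("one label per interval required")
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError(f"degenerate interval [{lo}, {hi})")
        for (_, hi1), (lo2, _) in zip(self.intervals, self.intervals[1:]):
            if lo2 < hi1:
                raise ValueError("intervals overlap or are out of order")

    @classmethod
    def from_range(cls, start: float, end: float, width: float) -> "AgeGroupScheme":
        """Decade-style bins, e.g. from_range(20, 80, 10) -> "20-30"..."70-80"."""
        if width <= 0 or end <= start:
            raise ValueError("need start < end and width > 0")
        edges = np.arange(start, end + width / 2, width)
        intervals = [(float(a), float(b)) for a, b in zip(edges, edges[1:])]
        labels = [f"{a:g}-{b:g}" for a, b in intervals]
        return cls(intervals=intervals, labels=labels)

    def assign(self, age: float) -> str | None:
        for (lo, hi), label in zip(self.intervals, self.labels):
            if lo <= age < hi:
                return label
        return None


def bin_ages(samples: SampleTable, scheme: AgeGroupScheme) -> pd.Series:
    """Group label per sample; samples outside every interval get NaN."""
    labels = [scheme.assign(a) for a in samples.ages]
    return pd.Series(labels, index=samples.data.index, name="age_group",
                     dtype=object)


def _student_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def sex_difference_by_group(m: BetaMatrix, samples: SampleTable,
                            scheme: AgeGroupScheme,
                            cpgs: Sequence[str] | None = None,
                            welch: bool = False) -> pd.DataFrame:
    """Per CpG and age group: mean(male) - mean(female) with a t-test p.

    Groups where either sex has fewer than 2 samples are marked
    incomparable (NaN difference and p).
    """
    m, samples = align_samples(m, samples)
    if cpgs is None:
        cpgs = m.cpg_ids
    group = bin_ages(samples, scheme)
    is_f = (samples.sex == "female").to_numpy()
    rows = []
    for label in scheme.labels:
        in_g = (group == label).to_numpy()
        sel_m, sel_f = in_g & ~is_f, in_g & is_f
        comparable = sel_m.sum() >= 2 and sel_f.sum() >= 2
        for cpg in cpgs:
            beta = m.values.loc[cpg].to_numpy(dtype=float)
            if comparable:
                diff = float(beta[sel_m].mean() - beta[sel_f].mean())
                p = _student_t(beta[sel_m], beta[sel_f], welch)
            else:
                diff, p = float("nan"), float("nan")
            rows.append({"cpg_id": cpg, "group": label, "mean_diff": diff,
                         "p": p, "comparable": comparable})
    return pd.DataFrame(rows)


def within_sex_vs_youngest(m: BetaMatrix, samples: SampleTable,
                           scheme: AgeGroupScheme,
                           cpgs: Sequence[str] | None = None,
                           welch: bool = False) -> pd.DataFrame:
    """For each sex, compare every older group against the youngest group.

    Returns one row per (cpg, sex, older group) with the mean methylation
    change relative to the youngest group and a t-test p-value; empty older
    groups are skipped.
    """
    m, samples = align_samples(m, samples)
    if cpgs is None:
        cpgs = m.cpg_ids
    group = bin_ages(samples, scheme).to_numpy()
    sex = samples.sex.to_numpy()
    youngest = scheme.labels[0]
    rows = []
    for sx in ("male", "female"):
        ref_sel = (group == youngest) & (sex == sx)
        if ref_sel.sum() < 2:
            raise ValueError(f"youngest group has <2 {sx} samples")
        for label in scheme.labels[1:]:
            sel = (group == label) & (sex == sx)
            if sel.sum() < 2:
                continue
            for cpg in cpgs:
                beta = m.values.loc[cpg].to_numpy(dtype=float)
                change = float(beta[sel].mean() - beta[ref_sel].mean())
                p = _student_t(beta[sel], beta[ref_sel], welch)
                rows.append({"cpg_id": cpg, "sex": sx, "group": label,
                             "mean_change": change, "p": p})
    return pd.DataFrame(rows)


def aggregate_sex_difference(m: BetaMatrix, samples: SampleTable,
                             scheme: AgeGroupScheme,
                             cpgs: Sequence[str] | None = None,
                             welch: bool = False) -> pd.DataFrame:
    """Sex difference per group on the across-CpG mean methylation profile."""
    m, samples = align_samples(m, samples)
    if cpgs is None:
        cpgs = m.cpg_ids
    profile = m.values.loc[list(cpgs)].mean(axis=0).to_numpy()
    group = bin_ages(samples, scheme).to_numpy()
    is_f = (samples.sex == "female").to_numpy()
    rows = []
    for label in scheme.labels:
        in_g = group == label
        sel_m, sel_f = in_g & ~is_f, in_g & is_f
        if sel_m.sum() >= 2 and sel_f.sum() >= 2:
            diff = float(profile[sel_m].mean() - profile[sel_f].mean())
            p = _student_t(profile[sel_m], profile[sel_f], welch)
        else:
            diff, p = float("nan"), float("nan")
        rows.append({"group": label, "mean_diff": diff, "p": p})
    return pd.DataFrame(rows)
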