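"""Beta-matrix preprocessing: missingness filter, KNN imputation, quantile
normalization.

The canonical pipeline order is filter -> impute -> normalize: the
missingness filter drops CpGs with too many absent cells, KNN imputation
fills the few that remain, and quantile normalization (which requires a
complete matrix) forces every sample column onto the common empirical
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .io import BetaMatrix


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing run."""

    n_cpgs_in: int
    n_cpgs_dropped_missing: int
    n_cells_imputed: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.n_cpgs_dropped_missing > self.n_cpgs_in:
            raise ValueError("dropped more CpGs than were present")
        if min(self.n_cpgs_in, self.n_cpgs_dropped_missing,
               self.n_cells_imputed) < 0:
            raise ValueError("counts must be non-negative")


def filter_missing(m: BetaMatrix, max_missing_frac: float = 0.05
                   ) -> tuple[BetaMatrix, PreprocessReport]:
    """Drop CpGs missing in *more than* ``max_missing_frac`` of samples.

    A CpG whose missing fraction equals the threshold exactly is retained
    (only strictly greater fractions are discarded).
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    if m.values.size == 0:
        raise ValueError("empty beta matrix")
    frac = m.values.isna().mean(axis=1)
    keep = frac.to_numpy() <= max_missing_frac
    out = BetaMatrix(m.values.loc[keep].copy())
    report = PreprocessReport(
        n_cpgs_in=m.shape[0],
        n_cpgs_dropped_missing=int((~keep).sum()),
    )
    return out, report


def knn_impute(m: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Fill missing cells from the k nearest CpG rows.

    Distances between CpG rows are Euclidean over the samples observed in
    both rows, rescaled by the fraction observed; the imputed value is the
    distance-weighted mean of the neighbours' values at that sample (the
    behaviour of the classic microarray KNN imputer). Imputed values are
    clipped to [0, 1]; observed cells are returned untouched. Rows without
    eligible donors fall back to their own observed mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(X)
    if not mask.any():
        return BetaMatrix(m.values.copy())
    if mask.all(axis=1).any():
        bad = m.values.index[mask.all(axis=1)][0]
        raise ValueError(f"CpG {bad!r} has no observed values; cannot impute")
    if mask.all(axis=0).any():
        bad = m.values.columns[mask.all(axis=0)][0]
        raise ValueError(f"sample {bad!r} has no observed values; cannot impute")

    n_rows = X.shape[0]
    k_eff = min(k, n_rows - 1)
    if k_eff < k:
        warnings.warn(
            f"k={k} exceeds the {n_rows - 1} candidate donor rows; using "
            f"k={k_eff}" if k_eff >= 1 else
            f"k={k} but no donor rows exist; falling back to row means",
            stacklevel=2,
        )
    if k_eff < 1:
        row_means = np.nanmean(X, axis=1)
        filled = np.where(mask, row_means[:, None], X)
    else:
        imputer = KNNImputer(n_neighbors=k_eff, weights="distance")
        filled = imputer.fit_transform(X)
        if filled.shape != X.shape:  # a feature was dropped: cannot happen after checks
            raise RuntimeError("imputer changed the matrix shape")
    filled = np.where(mask, np.clip(filled, 0.0, 1.0), X)
    out = pd.DataFrame(filled, index=m.values.index, columns=m.values.columns)
    return BetaMatrix(out)


def quantile_normalize(m: BetaMatrix) -> BetaMatrix:
    """Force every sample column onto the mean-of-sorted-columns distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values (the reference distribution); ties within a column receive
    the mean of the reference values spanning their tied ranks. Requires a
    complete matrix; the transform is idempotent and rank-preserving within
    columns.
    """
    X = m.values.to_numpy(dtype=float, copy=False)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute before "
                         "quantile normalization")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        idx = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[idx] = ref
        sorted_vals = col[idx]
        # average reference values across tied ranks
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and sorted_vals[stop] == sorted_vals[start]:
                stop += 1
            if stop - start > 1:
                assigned[idx[start:stop]] = ref[start:stop].mean()
            start = stop
        out[:, j] = assigned
    return BetaMatrix(pd.DataFrame(np.clip(out, 0.0, 1.0),
                                   index=m.values.index,
                                   columns=m.values.columns))


def preprocess(m: BetaMatrix, max_missing_frac: float = 0.05, k: int = 10,
               normalize: bool = True) -> tuple[BetaMatrix, PreprocessReport]:
    """Run the full filter -> impute -> (optionally) normalize pipeline."""
    filtered, report = filter_missing(m, max_missing_frac)
    n_missing = filtered.n_missing
    imputed = knn_impute(filtered, k=k) if n_missing else filtered
    report.n_cells_imputed = n_missing
    if normalize:
        imputed = quantile_normalize(imputed)
        report.normalized = True
    return imputed, report
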