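"""Gene-level enrichment of screened CpGs and methylation-expression
correlation.

CpGs are mapped to genes through the user-supplied annotation; disease
gene-set overrepresentation is assessed with the upper-tail hypergeometric
test on gene counts (each gene counted once however many CpGs hit it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CpGAnnotation, GeneSetCollection


@dataclass
class EnrichmentResult:
    set_name: str
    universe_size: int   # N
    set_size: int        # K = |geneset ∩ universe|
    selection_size: int  # n
    overlap: int         # k
    p_value: float       # P[X >= k], X ~ Hypergeom(N, K, n)
    fold: float          # (k/n) / (K/N)

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.selection_size):
            raise ValueError("overlap exceeds set or selection size")
        if min(self.universe_size, self.set_size, self.selection_size,
               self.overlap) < 0:
            raise ValueError("counts must be non-negative")


def map_cpgs_to_genes(cpgs: Iterable[str],
                      ann: CpGAnnotation) -> tuple[set[str], int]:
    """Union of annotated genes over the CpGs; also counts unannotated CpGs."""
    mapping = ann.mapping()
    genes: set[str] = set()
    n_unannotated = 0
    for cpg in cpgs:
        hit = mapping.get(cpg)
        if hit:
            genes |= hit
        else:
            n_unannotated += 1
    return genes, n_unannotated


def hypergeometric_enrichment(selection: set[str], geneset: set[str],
                              universe: set[str],
                              set_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``selection`` in ``geneset``.

    The gene set is first intersected with the universe; the selection must
    be a subset of the universe. ``p = P[X >= k]`` is computed with scipy's
    hypergeometric survival function (stable log-space tail evaluation).
    """
    offenders = selection - universe
    if offenders:
        raise ValueError(
            f"selection genes outside the universe: {sorted(offenders)[:5]}")
    N = len(universe)
    K = len(geneset & universe)
    n = len(selection)
    k = len(selection & geneset)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if N > 0 else 1.0
    expected = K * n / N if N else 0.0
    fold = (k / expected) if expected > 0 else float("nan")
    return EnrichmentResult(set_name=set_name, universe_size=N, set_size=K,
                            selection_size=n, overlap=k, p_value=min(p, 1.0),
                            fold=fold)


def enrich_gene_sets(selection: set[str], collection: GeneSetCollection,
                     universe: set[str]) -> pd.DataFrame:
    """Enrichment of every set in the collection against one selection."""
    rows = []
    for name in collection:
        r = hypergeometric_enrichment(selection, set(collection[name]),
                                      universe, set_name=name)
        rows.append({"set": r.set_name, "N": r.universe_size, "K": r.set_size,
                     "n": r.selection_size, "k": r.overlap, "fold": r.fold,
                     "p": r.p_value})
    return pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "fold", "p"])


def methylation_expression_correlation(meth: Sequence[float],
                                       expr: Sequence[float]
                                       ) -> tuple[float, float]:
    """Pearson correlation between a CpG's beta and its gene's expression.

    Returns (r, two-sided p). Requires >= 4 paired samples; a constant
    vector leaves r undefined and raises.
    """
    meth = np.asarray(meth, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if meth.size != expr.size:
        raise ValueError("paired vectors must have equal length")
    if meth.size < 4:
        raise ValueError("need at least 4 paired samples")
    if np.ptp(meth) == 0 or np.ptp(expr) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(meth, expr)
    return float(res.statistic), float(res.pvalue)
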