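"""Core containers and file I/O for methylation cohort data.

The central object is the :class:`BetaMatrix`, a CpG-by-sample matrix of
methylation beta values (methylated signal / total signal, bounded in
[0, 1], the HM450 convention), with ``NaN`` marking missing cells.
Alongside it live the per-sample covariate table (:class:`SampleTable`),
the CpG-to-gene annotation (:class:`CpGAnnotation`) and disease gene sets
read from GMT files (:class:`GeneSetCollection`).

All readers consume plain-text TSV/CSV/GMT; all writers emit TSV with a
header row. Missing beta values are written as ``NA``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: tokens accepted as "missing" in beta matrices (written back as "NA")
MISSING_TOKENS = ("NA", "NaN", "nan", "")

#: accepted spellings for the two sexes (configurable via read_sample_table)
SEX_SYNONYMS: Mapping[str, str] = {
    "M": "male", "male": "male", "Male": "male", "1": "male",
    "F": "female", "female": "female", "Female": "female", "2": "female",
}

_TRUE_TOKENS = {"1", "true", "True", "TRUE", "yes", "Yes", "Y"}
_FALSE_TOKENS = {"0", "false", "False", "FALSE", "no", "No", "N", ""}


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (range, uniqueness...)."""


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of beta values with an implicit missing mask.

    Parameters
    ----------
    values
        DataFrame with CpG ids as the index, sample ids as the columns and
        float values; ``NaN`` marks a missing cell. Every non-missing value
        must lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate CpG id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at "
                f"CpG {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    # -- basic views ----------------------------------------------------
    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset(self, cpgs: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "BetaMatrix":
        v = self.values
        if cpgs is not None:
            v = v.loc[list(cpgs)]
        if samples is not None:
            v = v[list(samples)]
        return BetaMatrix(v.copy())


@dataclass
class SampleTable:
    """Per-sample covariates: age (years), sex, optional exposure flags.

    ``data`` is indexed by sample id with an ``age`` column (float, years),
    a ``sex`` column holding ``"male"``/``"female"``, and any number of
    boolean exposure columns (e.g. ``drinker``, ``smoker``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        for col in ("age", "sex"):
            if col not in d.columns:
                raise ValidationError(f"sample table lacks required column {col!r}")
        ages = d["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or (ages < 0).any():
            raise ValidationError("ages must be finite and non-negative")
        bad_sex = set(d["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValidationError(f"unnormalized sex values {sorted(bad_sex)!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    @property
    def exposures(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("age", "sex")]

    def subset(self, samples: Iterable[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(samples)].copy())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CpGAnnotation:
    """CpG-to-gene mapping; one CpG may map to zero, one or several genes."""

    pairs: pd.DataFrame  # columns: cpg_id, gene

    def __post_init__(self) -> None:
        if self.pairs.duplicated().any():
            raise ValidationError("duplicate (cpg, gene) annotation pairs")

    def genes_for(self, cpg: str) -> set[str]:
        sel = self.pairs[self.pairs["cpg_id"] == cpg]
        return set(sel["gene"])

    def mapping(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cpg, gene in self.pairs.itertuples(index=False):
            out.setdefault(cpg, set()).add(gene)
        return out

    @property
    def all_genes(self) -> set[str]:
        return set(self.pairs["gene"])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. cardiovascular disease, stroke, hypertension)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if any(not g for g in genes):
                raise ValidationError(f"empty gene symbol in set {name!r}")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, delimiter: str | None = None) -> BetaMatrix:
    """Read a CpG-by-sample beta matrix from TSV/CSV.

    The first row holds sample ids, the first column CpG ids. Cells are
    numeric beta values in [0, 1] or one of the missing tokens
    (``NA``, ``NaN``, empty). Values outside [0, 1] raise
    :class:`ValidationError` naming the offending cell; non-numeric cells
    raise :class:`FormatError`.
    """
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0,
                         na_values=list(MISSING_TOKENS), keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"beta matrix {path} has no sample columns")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in beta matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path: str | Path,
                      delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    m.values.to_csv(path, sep=sep, na_rep="NA", index_label="cpg_id")


def read_sample_table(path: str | Path, delimiter: str | None = None,
                      sex_synonyms: Mapping[str, str] = SEX_SYNONYMS) -> SampleTable:
    """Read per-sample covariates (sample_id, age, sex, exposure flags).

    Sex tokens are normalized through ``sex_synonyms``; unknown tokens raise
    a :class:`ValidationError` listing the accepted spellings. Any column
    beyond ``age``/``sex`` is parsed as a boolean exposure flag.
    """
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse sample table {path}: {exc}") from exc
    for col in ("age", "sex"):
        if col not in df.columns:
            raise ValidationError(f"sample table {path} lacks column {col!r}")
    try:
        df["age"] = df["age"].astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric age in {path}: {exc}") from exc

    def _norm_sex(tok: str) -> str:
        if tok in sex_synonyms:
            return sex_synonyms[tok]
        raise ValidationError(
            f"unknown sex token {tok!r}; accepted: {sorted(set(sex_synonyms))}"
        )

    df["sex"] = df["sex"].map(_norm_sex)

    def _norm_bool(tok: str, col: str) -> bool:
        if tok in _TRUE_TOKENS:
            return True
        if tok in _FALSE_TOKENS:
            return False
        raise ValidationError(f"column {col!r}: cannot parse {tok!r} as boolean")

    for col in df.columns:
        if col in ("age", "sex"):
            continue
        df[col] = df[col].map(lambda t, c=col: _norm_bool(t, c))
    df.index = df.index.astype(str)
    return SampleTable(df)


def write_sample_table(t: SampleTable, path: str | Path,
                       delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    out = t.data.copy()
    for col in t.exposures:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep, index_label="sample_id")


def read_annotation(path: str | Path, delimiter: str | None = None) -> CpGAnnotation:
    """Read a two-column (cpg_id, gene) TSV; duplicate pairs are dropped."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"cpg_id", "gene"}.issubset(df.columns):
        raise FormatError(f"annotation {path} needs columns cpg_id, gene")
    df = df[["cpg_id", "gene"]].drop_duplicates().reset_index(drop=True)
    return CpGAnnotation(df)


def write_annotation(ann: CpGAnnotation, path: str | Path,
                     delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    ann.pairs.to_csv(path, sep=sep, index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gene_sets(coll: GeneSetCollection, path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in coll:
            genes = "\t".join(sorted(coll[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_samples(m: BetaMatrix, samples: SampleTable) -> tuple[BetaMatrix, SampleTable]:
    """Intersect and co-order the samples of a matrix and covariate table.

    Sample order follows the beta matrix columns. If the two inputs share no
    sample ids but the covariate ids match the matrix *rows*, the matrix is
    assumed to be transposed and an error is raised rather than guessing.
    """
    common = [s for s in m.sample_ids if s in set(samples.sample_ids)]
    if not common:
        if set(samples.sample_ids) & set(m.cpg_ids):
            raise ValidationError(
                "beta matrix appears transposed: sample ids match its rows; "
                "expected CpGs as rows and samples as columns"
            )
        raise ValidationError("beta matrix and sample table share no sample ids")
    return m.subset(samples=common), samples.subset(common)
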