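"""On-disk artifacts and the shared data model.

Count matrices are gene x sample tables of non-negative measurements
(integer counts or FPKM-like reals).  Design tables carry per-sample
phenotype and known adjustment variables.  Everything round-trips through
plain TSV (and MatrixMarket for sparse counts) so artifacts stay diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class SvaseqError(ValueError):
    """Base error for invalid inputs or invariant violations."""


@dataclasses.dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative expression measurements.

    Parameters
    ----------
    values : ndarray of shape (m_genes, n_samples)
        Non-negative, finite counts or FPKM values.
    gene_ids, sample_ids : sequences of unique strings
        Row and column identifiers.
    unit_tag : {"counts", "fpkm"}
        Records what the values are; no computation branches on it.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise SvaseqError("count matrix must be 2-dimensional")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise SvaseqError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise SvaseqError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            dup = _first_duplicate(self.gene_ids)
            raise SvaseqError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise SvaseqError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise SvaseqError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise SvaseqError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.unit_tag not in ("counts", "fpkm"):
            raise SvaseqError(f"unknown unit_tag {self.unit_tag!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[keep],
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.unit_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclasses.dataclass
class DesignInfo:
    """Per-sample primary phenotype and known adjustment variables.

    ``full_design`` is intercept + primary + known adjustment columns;
    ``null_design`` drops the primary block.  Categorical variables are
    treatment-coded against the lexicographically first level.
    """

    sample_ids: list[str]
    primary: pd.DataFrame
    known_adjust: pd.DataFrame
    full_design: np.ndarray = dataclasses.field(init=False)
    null_design: np.ndarray = dataclasses.field(init=False)
    column_names: list[str] = dataclasses.field(init=False)
    primary_slice: slice = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise SvaseqError("duplicate sample id in design")
        prim = _encode(self.primary, n, "primary")
        adj = _encode(self.known_adjust, n, "adjust")
        intercept = pd.DataFrame({"intercept": np.ones(n)})
        full = pd.concat(
            [d.reset_index(drop=True) for d in (intercept, prim, adj)], axis=1
        )
        null = pd.concat(
            [d.reset_index(drop=True) for d in (intercept, adj)], axis=1
        )
        self.full_design = full.to_numpy(dtype=float)
        self.null_design = null.to_numpy(dtype=float)
        self.column_names = list(full.columns)
        self.primary_slice = slice(1, 1 + prim.shape[1])
        if np.linalg.matrix_rank(self.full_design) < self.full_design.shape[1]:
            raise SvaseqError(
                "full design is rank deficient (collinear primary/adjustment "
                "variables)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_primary(self) -> int:
        return self.primary_slice.stop - self.primary_slice.start

    def primary_columns(self) -> np.ndarray:
        return self.full_design[:, self.primary_slice]

    def check_samples(self, counts: CountMatrix) -> None:
        """Require exact sample id match, in order, with a count matrix."""
        if self.sample_ids != counts.sample_ids:
            raise SvaseqError(
                "design sample ids do not match count matrix sample ids "
                f"({self.sample_ids[:3]}... vs {counts.sample_ids[:3]}...)"
            )


@dataclasses.dataclass
class GeneSet:
    """A set of gene identifiers with a role tag (e.g. negative controls)."""

    ids: frozenset[str]
    role_tag: str = "negative_control"

    def __post_init__(self) -> None:
        self.ids = frozenset(str(g) for g in self.ids)
        if self.role_tag not in ("negative_control", "empirical_control", "other"):
            raise SvaseqError(f"unknown role_tag {self.role_tag!r}")

    def mask(self, counts: CountMatrix) -> np.ndarray:
        """Boolean per-gene membership mask; errors if disjoint from counts."""
        mask = np.array([g in self.ids for g in counts.gene_ids])
        if not mask.any():
            raise SvaseqError("gene set is disjoint from the count matrix gene ids")
        return mask


@dataclasses.dataclass
class LatentFactors:
    """n_samples x Q matrix of surrogate variables (estimated or true)."""

    values: np.ndarray
    factor_ids: list[str] = dataclasses.field(default_factory=list)
    kind: str = "estimated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not self.factor_ids:
            self.factor_ids = [f"SV{q + 1}" for q in range(self.values.shape[1])]
        if len(self.factor_ids) != self.values.shape[1]:
            raise SvaseqError("factor_ids length does not match Q")
        if self.kind not in ("estimated", "true"):
            raise SvaseqError(f"unknown factor kind {self.kind!r}")

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _encode(df: pd.DataFrame | None, n: int, label: str) -> pd.DataFrame:
    """Treatment-code categoricals, lexicographically first level as reference."""
    if df is None or df.shape[1] == 0:
        return pd.DataFrame(index=range(n))
    if len(df) != n:
        raise SvaseqError(f"{label} table has {len(df)} rows for {n} samples")
    out: dict[str, np.ndarray] = {}
    for col in df.columns:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise SvaseqError(f"missing/non-finite value in {label} column {col!r}")
            out[str(col)] = vals
        else:
            if series.isna().any():
                raise SvaseqError(f"missing value in {label} column {col!r}")
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                out[f"{col}[{level}]"] = (series.astype(str) == level).to_numpy(float)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str = "tsv", unit_tag: str = "counts") -> CountMatrix:
    """Read a gene x sample count matrix.

    TSV dialect: first column gene ids, header row sample ids.  MTX dialect:
    MatrixMarket coordinate file with sibling ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` id lists (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            row, col = next(
                (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
            )
            raise SvaseqError(f"missing value at gene {row!r}, sample {col!r} in {path}")
        return CountMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                           list(df.columns.astype(str)), unit_tag)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                           dtype=float)
        stem = path.with_suffix("")
        genes = _read_id_list(Path(f"{stem}.rows.txt"))
        samples = _read_id_list(Path(f"{stem}.cols.txt"))
        return CountMatrix(dense, genes, samples, unit_tag)
    raise SvaseqError(f"unknown count format {format!r}")


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as TSV at full double precision."""
    counts.to_frame().to_csv(Path(path), sep="\t", index_label="gene_id",
                             float_format="%.17g")


def read_design(
    path: str | Path,
    primary_cols: Sequence[str],
    adjust_cols: Sequence[str] = (),
    counts: CountMatrix | None = None,
) -> DesignInfo:
    """Read a sample design table (TSV with a ``sample_id`` column).

    If ``counts`` is given, rows are re-ordered to the count matrix's sample
    order (the counts file is authoritative); unknown or missing samples are
    an error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SvaseqError("design table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    if counts is not None:
        missing = [s for s in counts.sample_ids if s not in df.index]
        if missing:
            raise SvaseqError(f"design table lacks samples {missing[:5]}")
        df = df.loc[counts.sample_ids]
    for col in list(primary_cols) + list(adjust_cols):
        if col not in df.columns:
            raise SvaseqError(f"design table lacks column {col!r}")
    design = DesignInfo(
        sample_ids=list(df.index),
        primary=df[list(primary_cols)],
        known_adjust=df[list(adjust_cols)],
    )
    if counts is not None:
        design.check_samples(counts)
    return design


def read_gene_list(path: str | Path, role_tag: str = "negative_control") -> GeneSet:
    """Read a plain-text gene list (one id per line, '#' comments)."""
    return GeneSet(frozenset(_read_id_list(Path(path))), role_tag)


def _read_id_list(path: Path) -> list[str]:
    ids: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def write_factors(factors: LatentFactors, sample_ids: Sequence[str],
                  path: str | Path) -> None:
    """Write latent factors as a sample x Q TSV (header always present)."""
    pd.DataFrame(factors.values, index=list(sample_ids),
                 columns=factors.factor_ids).to_csv(
        Path(path), sep="\t", index_label="sample_id", float_format="%.17g")


def read_factors(path: str | Path, kind: str = "estimated") -> tuple[LatentFactors, list[str]]:
    """Read a factors TSV back; returns (factors, sample_ids)."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    values = df.to_numpy(dtype=float).reshape(len(df), -1)
    return (LatentFactors(values, list(df.columns.astype(str)), kind),
            list(df.index.astype(str)))


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Generic TSV writer at full double precision."""
    df.to_csv(Path(path), sep="\t", index=index_label is not None,
              index_label=index_label, float_format="%.17g")
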