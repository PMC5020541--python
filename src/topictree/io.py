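"""Reading expression matrices and preparing them for topic modelling.

Expression values arrive as a genes x cells matrix (dense TSV/CSV, or
MatrixMarket coordinate format with sidecar name files).  Before an LDA
model can be fitted the values are log-transformed, low-variance genes are
dropped, and the remaining values are rounded to the integer "word counts"
the topic model consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Input file violates the expected dialect (duplicate ids, bad shape)."""


class EmptyModelError(ValueError):
    """A filtering step removed every gene."""


class DegenerateCellError(ValueError):
    """A cell ends up with zero total count and cannot enter the model."""


@dataclass
class ExpressionMatrix:
    """Genes x cells real-valued expression with identifiers and optional groups.

    Parameters
    ----------
    values : (V, M) float array, finite and non-negative.
    gene_ids, cell_ids : unique identifiers for rows / columns.
    groups : optional mapping cell_id -> group label (e.g. sampling time).
    group_order : optional ordered list of the group labels.
    provenance : record of transforms already applied (guards double pretreat).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    groups: dict[str, str] | None = None
    group_order: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.groups is not None:
            missing = set(self.cell_ids) - set(self.groups)
            if missing:
                raise KeyError(f"cells without group label: {sorted(missing)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class CountMatrix:
    """Non-negative integer genes x cells counts for the topic model."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    groups: dict[str, str] | None = None
    group_order: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("count shape does not match identifier lists")
        col_sums = self.counts.sum(axis=0)
        if np.any(col_sums == 0):
            bad = [self.cell_ids[i] for i in np.nonzero(col_sums == 0)[0]]
            raise DegenerateCellError(f"cells with zero total count: {bad}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_groups(path: str | Path, order_path: str | Path | None = None,
                known_cells: Sequence[str] | None = None
                ) -> tuple[dict[str, str], list[str] | None]:
    """Read a two-column TSV (cell_id, label); optional group-order file."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("group file needs two columns: cell_id<TAB>label")
    groups = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if known_cells is not None:
        unknown = set(groups) - set(map(str, known_cells))
        if unknown:
            raise KeyError(f"group file names unknown cells: {sorted(unknown)[:5]}")
    order = None
    if order_path is not None:
        order = [ln.strip() for ln in Path(order_path).read_text().splitlines()
                 if ln.strip()]
    return groups, order


def read_expression(path: str | Path, format: str = "tsv",
                    groups_path: str | Path | None = None,
                    group_order_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``tsv``/``csv``: first column gene ids, header row of cell ids.
    ``mtx``: MatrixMarket coordinate file with sidecar ``<stem>.genes.txt``
    and ``<stem>.cells.txt`` (one name per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            raise FormatError("duplicate gene identifiers in file")
        if df.columns.has_duplicates:
            raise FormatError("duplicate cell identifiers in file")
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        stem = path.with_suffix("")
        gene_ids = [ln.strip() for ln in
                    Path(f"{stem}.genes.txt").read_text().splitlines() if ln.strip()]
        cell_ids = [ln.strip() for ln in
                    Path(f"{stem}.cells.txt").read_text().splitlines() if ln.strip()]
    else:
        raise ValueError(f"unknown format {format!r}; expected tsv, csv or mtx")

    groups = order = None
    if groups_path is not None:
        groups, order = read_groups(groups_path, group_order_path, cell_ids)
        groups = {c: groups[c] for c in cell_ids if c in groups}
        if set(groups) != set(cell_ids):
            missing = set(cell_ids) - set(groups)
            raise KeyError(f"cells without group label: {sorted(missing)[:5]}")
    return ExpressionMatrix(values, gene_ids, cell_ids, groups, order)


def write_expression_tsv(m: ExpressionMatrix | CountMatrix, path: str | Path) -> None:
    values = m.values if isinstance(m, ExpressionMatrix) else m.counts
    pd.DataFrame(values, index=m.gene_ids, columns=m.cell_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pre-treatment and discretisation
# ---------------------------------------------------------------------------

def pretreat(m: ExpressionMatrix, sd_threshold: float = 0.5,
             log_base: float = 2.0) -> ExpressionMatrix:
    """Log-transform and drop low-variability genes.

    Values become ``log(1 + x) / log(log_base)``; genes whose post-transform
    standard deviation across cells (ddof=1) falls below ``sd_threshold`` are
    removed.  A second call on an already pre-treated matrix raises, because
    double log-transformation silently corrupts the scale.
    """
    if m.provenance.get("pretreated"):
        raise ValueError("matrix already pre-treated; refusing to log-transform twice")
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be >= 0")
    if log_base <= 1:
        raise ValueError("log_base must be > 1")
    logged = np.log1p(m.values) / math.log(log_base)
    if m.n_cells > 1:
        sds = logged.std(axis=1, ddof=1)
    else:
        sds = np.zeros(m.n_genes)
    keep = sds >= sd_threshold
    if not keep.any():
        raise EmptyModelError(
            f"no gene has standard deviation >= {sd_threshold}; lower the threshold")
    prov = dict(m.provenance)
    prov.update(pretreated=True, sd_threshold=sd_threshold, log_base=log_base,
                genes_before=m.n_genes, genes_after=int(keep.sum()))
    return ExpressionMatrix(
        logged[keep], [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.cell_ids), m.groups, m.group_order, prov)


def discretise(m: ExpressionMatrix, scale: float = 1.0) -> CountMatrix:
    """Round (scaled) expression values half-up to the integer counts LDA uses."""
    if np.any(m.values < 0):
        raise ValueError("discretise expects non-negative (pre-treated) values")
    # half-up rounding: floor(x + 0.5), not banker's rounding
    counts = np.floor(m.values * scale + 0.5).astype(np.int64)
    prov = dict(m.provenance)
    prov.update(discretised="round-half-up", scale=scale)
    return CountMatrix(counts, list(m.gene_ids), list(m.cell_ids),
                       m.groups, m.group_order, prov)
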