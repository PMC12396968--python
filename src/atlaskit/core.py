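"""Canonical data structures, normalization, depth equalization and file I/O.

A :class:`CellMatrix` bundles sparse GEX (and optionally ADT) counts with
cell and gene metadata.  On-disk representation is a plain-text bundle:
Matrix Market files for the counts, TSV for metadata, and a JSON sidecar
fixing categorical level order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

#: Canonical coarse tissue groups used throughout the pipeline.
TISSUE_GROUPS = ("BLO", "BM", "SPL", "LN", "LNG", "JEJ")

#: Default mapping of fine sampling sites to coarse tissue groups:
#: jejunum lamina propria / epithelium pool into the gut group, airway
#: lavage and lung parenchyma into the lung group, and the three lymph-node
#: stations into a single node group.  Config-driven, not hard-coded in
#: downstream stages.
DEFAULT_SITE_TO_GROUP = {
    "BLO": "BLO",
    "BM": "BM",
    "SPL": "SPL",
    "ILN": "LN",
    "LLN": "LN",
    "MLN": "LN",
    "BAL": "LNG",
    "PAR": "LNG",
    "JEL": "JEJ",
    "JLP": "JEJ",
}

#: Names of per-gene nuisance-list membership flags in ``gene_meta``.
NUISANCE_FLAGS = (
    "is_heat_shock",
    "is_ribosomal",
    "is_metallothionein",
    "is_hemoglobin",
    "is_stress",
)

REQUIRED_CELL_COLUMNS = ("donor_id", "tissue_group")


class CellMatrixError(ValueError):
    """Structural problem in a CellMatrix or its on-disk bundle."""


@dataclass
class CellMatrix:
    """Sparse cell x gene (and optional cell x ADT) counts plus metadata.

    Attributes
    ----------
    gex_counts
        Nonnegative integer sparse matrix, cells x genes.
    adt_counts
        Optional nonnegative integer sparse matrix, cells x ADT markers.
    cell_meta
        One row per cell.  Must carry ``donor_id`` and ``tissue_group``;
        typically also tissue, lineage, subset, age_group, sex, cmv, site
        and chemistry.
    gene_meta
        One row per gene with a unique ``symbol`` column and boolean
        nuisance-list flags (see :data:`NUISANCE_FLAGS`).
    adt_meta
        Optional one row per ADT marker (``marker`` column).
    qc_flags
        Optional per-cell table of upstream QC outputs (doublet
        probabilities, erythrocyte fraction, dual-receptor flag, ...).
    """

    gex_counts: sp.spmatrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    adt_counts: sp.spmatrix | None = None
    adt_meta: pd.DataFrame | None = None
    qc_flags: pd.DataFrame | None = None
    truth: object = None  # populated by the synthetic generator

    def __post_init__(self) -> None:
        self.gex_counts = sp.csr_matrix(self.gex_counts)
        if self.adt_counts is not None:
            self.adt_counts = sp.csr_matrix(self.adt_counts)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.gex_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.gex_counts.shape[1]

    def validate(self) -> None:
        if self.gex_counts.nnz and self.gex_counts.data.min() < 0:
            raise CellMatrixError("gex_counts contains negative entries")
        if len(self.cell_meta) != self.gex_counts.shape[0]:
            raise CellMatrixError(
                f"cell_meta has {len(self.cell_meta)} rows but the count "
                f"matrix has {self.gex_counts.shape[0]} cells"
            )
        if len(self.gene_meta) != self.gex_counts.shape[1]:
            raise CellMatrixError(
                f"gene_meta has {len(self.gene_meta)} rows but the count "
                f"matrix has {self.gex_counts.shape[1]} genes"
            )
        for col in REQUIRED_CELL_COLUMNS:
            if col not in self.cell_meta.columns:
                raise CellMatrixError(f"cell_meta missing required column {col!r}")
            vals = self.cell_meta[col]
            if vals.isna().any() or (vals.astype(str) == "").any():
                raise CellMatrixError(f"cell_meta column {col!r} has empty values")
        if self.gene_meta["symbol"].duplicated().any():
            dups = self.gene_meta["symbol"][self.gene_meta["symbol"].duplicated()]
            raise CellMatrixError(f"duplicate gene symbols: {sorted(set(dups))[:5]}")
        if self.adt_counts is not None:
            if self.adt_counts.shape[0] != self.gex_counts.shape[0]:
                raise CellMatrixError("adt_counts cell dimension mismatch")
        unknown = set(self.cell_meta["tissue_group"].astype(str)) - set(TISSUE_GROUPS)
        if unknown:
            warnings.warn(
                f"unknown tissue_group values pass through: {sorted(unknown)}",
                stacklevel=2,
            )

    def gene_index(self, symbols) -> np.ndarray:
        """Column indices of the given gene symbols (raises on misses)."""
        lookup = pd.Index(self.gene_meta["symbol"])
        idx = lookup.get_indexer(list(symbols))
        if (idx < 0).any():
            missing = [s for s, i in zip(symbols, idx) if i < 0]
            raise KeyError(f"genes not present: {missing[:5]}")
        return idx


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``ln(scale * c / T + 1)``.

    ``scale`` is 10,000 for GEX and 1,000 for ADT by convention.  Natural
    log throughout (the dominant single-cell convention; the choice is a
    documented constant, not configurable per call).
    """

    values: sp.spmatrix | np.ndarray
    scale: float
    log_base: float = float(np.e)

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)


def normalize_counts(
    counts: sp.spmatrix | np.ndarray,
    total_per_cell: np.ndarray | None = None,
    scale: float = 10_000.0,
) -> NormalizedMatrix:
    """Depth-normalize and log-transform a count matrix.

    value = ln(scale * c / T + 1) where T is the cell's total count.
    Zero counts stay exactly zero (sparsity is preserved).

    Raises
    ------
    ValueError
        If any retained cell has zero total counts; callers must filter
        empty cells first.  The error lists the offending cell indices.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    X = sp.csr_matrix(counts, dtype=np.float64)
    if total_per_cell is None:
        total_per_cell = np.asarray(X.sum(axis=1)).ravel()
    total_per_cell = np.asarray(total_per_cell, dtype=np.float64).ravel()
    if total_per_cell.shape[0] != X.shape[0]:
        raise ValueError("total_per_cell length must equal number of cells")
    zero = np.flatnonzero(total_per_cell <= 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"indices {zero[:10].tolist()}"
        )
    out = X.copy()
    # scale each row by scale/T, then log1p on stored entries only
    row_scale = scale / total_per_cell
    out.data *= np.repeat(row_scale, np.diff(out.indptr))
    np.log1p(out.data, out=out.data)
    return NormalizedMatrix(values=out, scale=float(scale))


def downsample_equal_depth(
    counts: sp.spmatrix | np.ndarray,
    group_labels,
    seed: int,
    method: str = "binomial",
) -> sp.csr_matrix:
    """Equalize mean sequencing depth across groups by random thinning.

    Every group is thinned toward the minimum group-mean depth: each cell's
    counts are binomially thinned at rate ``target_mean / group_mean``
    (``method="binomial"``, default) or each cell is subsampled to an exact
    multinomial draw of ``round(rate * cell_total)`` transcripts
    (``method="multinomial"``).  Output counts never exceed input counts and
    the zero pattern is preserved.
    """
    X = sp.csr_matrix(counts, dtype=np.int64)
    labels = np.asarray(group_labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("group_labels length must equal number of cells")
    cell_totals = np.asarray(X.sum(axis=1)).ravel()
    rng = np.random.default_rng(seed)

    groups = pd.unique(labels)
    means = {}
    for g in groups:
        tot = cell_totals[labels == g]
        if tot.sum() == 0:
            raise ValueError(f"group {g!r} has zero total counts")
        means[g] = tot.mean()
    target = min(means.values())

    out = X.tocoo()
    data = out.data.copy()
    rates = np.array([target / means[g] for g in labels[out.row]])
    if method == "binomial":
        thin = rates < 1 - 1e-12
        data[thin] = rng.binomial(out.data[thin], rates[thin])
    elif method == "multinomial":
        # exact per-cell subsample to round(rate * total) transcripts
        csr = X
        new_data = csr.data.copy()
        for i in range(X.shape[0]):
            rate = target / means[labels[i]]
            if rate >= 1 - 1e-12:
                continue
            sl = slice(csr.indptr[i], csr.indptr[i + 1])
            row = csr.data[sl]
            n_keep = int(round(rate * row.sum()))
            kept = rng.multivariate_hypergeometric(row, n_keep)
            new_data[sl] = kept
        res = sp.csr_matrix(
            (new_data, csr.indices.copy(), csr.indptr.copy()), shape=X.shape
        )
        res.eliminate_zeros()
        return res
    else:
        raise ValueError(f"unknown method {method!r}")
    res = sp.coo_matrix((data, (out.row, out.col)), shape=X.shape).tocsr()
    res.eliminate_zeros()
    return res


# ---------------------------------------------------------------------------
# I/O: Matrix Market + TSV bundle
# ---------------------------------------------------------------------------

_BUNDLE = {
    "gex": "matrix.mtx",
    "adt": "adt.mtx",
    "cells": "cells.tsv",
    "genes": "genes.tsv",
    "adts": "adts.tsv",
    "qc": "qc_flags.tsv",
    "categories": "categories.json",
}


def write_cell_matrix(path, matrix: CellMatrix) -> None:
    """Write a CellMatrix bundle (mtx + TSV + JSON sidecar) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / _BUNDLE["gex"], sp.coo_matrix(matrix.gex_counts))
    matrix.cell_meta.to_csv(path / _BUNDLE["cells"], sep="\t", index=False)
    matrix.gene_meta.to_csv(path / _BUNDLE["genes"], sep="\t", index=False)
    if matrix.adt_counts is not None:
        scipy.io.mmwrite(path / _BUNDLE["adt"], sp.coo_matrix(matrix.adt_counts))
        if matrix.adt_meta is not None:
            matrix.adt_meta.to_csv(path / _BUNDLE["adts"], sep="\t", index=False)
    if matrix.qc_flags is not None:
        matrix.qc_flags.to_csv(path / _BUNDLE["qc"], sep="\t", index=False)
    cats = {
        col: matrix.cell_meta[col].cat.categories.tolist()
        for col in matrix.cell_meta.columns
        if isinstance(matrix.cell_meta[col].dtype, pd.CategoricalDtype)
    }
    (path / _BUNDLE["categories"]).write_text(json.dumps(cats, indent=1))


def read_cell_matrix(path) -> CellMatrix:
    """Read a CellMatrix bundle written by :func:`write_cell_matrix`."""
    path = Path(path)
    for key, fname in (("gex", _BUNDLE["gex"]), ("cells", _BUNDLE["cells"]),
                       ("genes", _BUNDLE["genes"])):
        if not (path / fname).exists():
            raise CellMatrixError(f"required bundle file missing: {fname}")
    gex = sp.csr_matrix(scipy.io.mmread(path / _BUNDLE["gex"]))
    cell_meta = pd.read_csv(path / _BUNDLE["cells"], sep="\t")
    gene_meta = pd.read_csv(path / _BUNDLE["genes"], sep="\t")
    if len(cell_meta) != gex.shape[0]:
        raise CellMatrixError(
            f"{_BUNDLE['cells']}: {len(cell_meta)} rows do not match "
            f"{gex.shape[0]} matrix rows"
        )
    if len(gene_meta) != gex.shape[1]:
        raise CellMatrixError(
            f"{_BUNDLE['genes']}: {len(gene_meta)} rows do not match "
            f"{gex.shape[1]} matrix columns"
        )
    cat_file = path / _BUNDLE["categories"]
    if cat_file.exists():
        cats = json.loads(cat_file.read_text())
        for col, levels in cats.items():
            if col in cell_meta.columns:
                cell_meta[col] = pd.Categorical(cell_meta[col], categories=levels)
    adt = None
    adt_meta = None
    if (path / _BUNDLE["adt"]).exists():
        adt = sp.csr_matrix(scipy.io.mmread(path / _BUNDLE["adt"]))
        if (path / _BUNDLE["adts"]).exists():
            adt_meta = pd.read_csv(path / _BUNDLE["adts"], sep="\t")
    qc = None
    if (path / _BUNDLE["qc"]).exists():
        qc = pd.read_csv(path / _BUNDLE["qc"], sep="\t")
        if len(qc) != gex.shape[0]:
            raise CellMatrixError(
                f"{_BUNDLE['qc']}: {len(qc)} rows do not match matrix rows"
            )
    return CellMatrix(
        gex_counts=gex,
        cell_meta=cell_meta,
        gene_meta=gene_meta,
        adt_counts=adt,
        adt_meta=adt_meta,
        qc_flags=qc,
    )
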