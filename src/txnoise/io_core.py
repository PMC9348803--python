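"""Sparse count-matrix I/O and the shared data model.

The package works on 10x-style sparse UMI matrices: a Matrix Market
coordinate file with genes as rows and cells as columns, accompanied by
one-per-line gene and barcode tables and a tab-delimited per-cell metadata
table. Every downstream stage consumes the :class:`CountMatrix` /
:class:`NormalizedMatrix` containers defined here.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSet",
    "FormatError",
    "MetadataError",
    "read_mtx",
    "read_mtx_dir",
    "write_mtx",
    "load_gene_set",
    "GENOTYPES",
    "TIMEPOINTS",
    "META_COLUMNS",
]

GENOTYPES = ("WT", "NULL")
TIMEPOINTS = ("2mo", "4mo")
#: required per-cell metadata columns (beyond the barcode index)
META_COLUMNS = ("sample_id", "genotype", "timepoint")

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"
META_FILE = "meta.tsv"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class MetadataError(ValueError):
    """Cell metadata is missing, incomplete, or inconsistent."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} {dup!r}")


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with identifiers and cell metadata.

    Parameters
    ----------
    counts
        Sparse (or dense) non-negative integer matrix, genes as rows.
    gene_ids
        Unique gene symbols, one per row.
    barcodes
        Unique cell barcodes, one per column.
    cell_meta
        DataFrame indexed by barcode with columns ``sample_id``,
        ``genotype`` (``WT``/``NULL``) and ``timepoint`` (``2mo``/``4mo``).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        _check_unique(list(self.gene_ids), "gene id")
        _check_unique(list(self.barcodes), "barcode")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("counts contain negative entries")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise FormatError("counts contain non-integer entries")
                self.counts = self.counts.astype(np.int64)
        self._validate_meta()

    def _validate_meta(self) -> None:
        meta = self.cell_meta
        if not isinstance(meta, pd.DataFrame):
            raise MetadataError("cell_meta must be a DataFrame indexed by barcode")
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise MetadataError(f"cell_meta missing columns {missing_cols}")
        missing = set(self.barcodes) - set(meta.index)
        if missing:
            raise MetadataError(
                f"{len(missing)} barcodes missing from metadata, "
                f"e.g. {sorted(missing)[:3]}"
            )
        sub = meta.loc[list(self.barcodes), list(META_COLUMNS)]
        if sub.isna().any().any():
            raise MetadataError("cell_meta contains missing values")
        bad_gt = set(sub["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise MetadataError(f"unknown genotype values {sorted(bad_gt)}")
        bad_tp = set(sub["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise MetadataError(f"unknown timepoint values {sorted(bad_tp)}")
        # keep only the cells in this matrix, in column order
        self.cell_meta = sub

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def total_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            list(self.gene_ids) == list(other.gene_ids)
            and list(self.barcodes) == list(other.barcodes)
            and (self.counts != other.counts).nnz == 0
            and self.cell_meta.equals(other.cell_meta)
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression on the same axes as its source counts.

    ``values[g, c] = log1p(count[g, c] * scale_factor / total_counts[c])``
    with the natural logarithm, so zero counts stay exactly zero and the
    matrix remains sparse.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError("normalized matrix axes do not match identifiers")
        if self.values.data.size and self.values.data.min() < 0:
            raise FormatError("normalized values must be non-negative")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices for the given gene symbols (error on absent genes)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def dense_rows(self, genes: Sequence[str]) -> np.ndarray:
        """Dense (len(genes) x n_cells) block for the requested genes."""
        return np.asarray(self.values[self.gene_index(genes), :].todense())

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
            scale_factor=self.scale_factor,
        )

    def subset_genes(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[idx, :],
            gene_ids=self.gene_ids[idx],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta,
            scale_factor=self.scale_factor,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene symbols."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_lines(path: os.PathLike | str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_mtx(
    matrix_path: os.PathLike | str,
    genes_path: os.PathLike | str,
    barcodes_path: os.PathLike | str,
    meta_path: os.PathLike | str,
) -> CountMatrix:
    """Read a Matrix Market count matrix plus gene/barcode/metadata tables.

    Genes are rows and cells are columns. Entry order in the coordinate
    file is irrelevant. Raises :class:`FormatError` on dimension mismatch
    or non-integer entries and :class:`MetadataError` when a barcode is
    absent from the metadata table.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.issubdtype(mat.data.dtype, np.integer):
        if not np.array_equal(mat.data, np.round(mat.data)):
            raise FormatError(f"{matrix_path} contains non-integer entries")
        mat = mat.astype(np.int64)

    gene_ids = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    if len(gene_ids) != mat.shape[0]:
        raise FormatError(
            f"matrix header declares {mat.shape[0]} genes but "
            f"{genes_path} has {len(gene_ids)} entries"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"matrix header declares {mat.shape[1]} cells but "
            f"{barcodes_path} has {len(barcodes)} entries"
        )

    # keep_default_na=False: the literal string "NULL" is a genotype here
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    if "barcode" not in meta.columns:
        raise MetadataError(f"{meta_path} lacks a 'barcode' column")
    if meta["barcode"].duplicated().any():
        raise MetadataError(f"{meta_path} contains duplicate barcodes")
    meta = meta.set_index("barcode")

    return CountMatrix(
        counts=mat.tocsr(),
        gene_ids=np.array(gene_ids, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )


def read_mtx_dir(directory: os.PathLike | str) -> CountMatrix:
    """Read the ``matrix.mtx`` / ``genes.tsv`` / ``barcodes.tsv`` /
    ``meta.tsv`` quartet from one directory."""
    d = Path(directory)
    return read_mtx(
        d / MATRIX_FILE, d / GENES_FILE, d / BARCODES_FILE, d / META_FILE
    )


def write_mtx(cm: CountMatrix, out_dir: os.PathLike | str) -> dict[str, Path]:
    """Write a CountMatrix as the four-file MTX bundle ``read_mtx`` reads.

    Returns the paths written. The matrix header is the standard
    ``%%MatrixMarket matrix coordinate integer general`` with genes as rows.
    """
    cm.validate()
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": d / MATRIX_FILE,
        "genes": d / GENES_FILE,
        "barcodes": d / BARCODES_FILE,
        "meta": d / META_FILE,
    }
    coo = cm.counts.tocoo().astype(np.int64)
    buf = io.BytesIO()
    scipy.io.mmwrite(
        buf,
        coo,
        comment="genes x cells UMI counts",
        field="integer",
    )
    paths["matrix"].write_bytes(buf.getvalue())
    paths["genes"].write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    paths["barcodes"].write_text("\n".join(map(str, cm.barcodes)) + "\n")
    meta = cm.cell_meta.loc[list(cm.barcodes), list(META_COLUMNS)]
    meta.to_csv(paths["meta"], sep="\t", index_label="barcode")
    return paths


def load_gene_set(path: os.PathLike | str, name: str | None = None) -> GeneSet:
    """Load a gene set from a plain-text file, one symbol per line.

    Blank lines are ignored, surrounding whitespace is stripped, and
    duplicate symbols are collapsed. An empty file is an error.
    """
    symbols = _read_lines(path)
    if not symbols:
        raise FormatError(f"gene set file {path} is empty")
    return GeneSet(name=name or Path(path).stem, members=frozenset(symbols))
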