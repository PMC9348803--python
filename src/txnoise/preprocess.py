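"""Cell QC filtering and library-size log-normalization.

Quality control follows the minimal rule used for droplet UMI data of this
depth: a cell is kept iff it detects at least ``min_genes`` genes
(default 500). No mitochondrial-fraction or doublet filter is applied;
the per-cell mitochondrial percentage can be reported but is a dataset
property here, not a threshold. Genes with zero total count across the
retained cells are removed before any statistic that divides by the mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import CountMatrix, NormalizedMatrix

__all__ = [
    "EmptyResultError",
    "filter_cells",
    "drop_unexpressed_genes",
    "normalize",
    "qc_report",
]


class EmptyResultError(ValueError):
    """A filtering step removed every cell, so downstream stages cannot run."""


def filter_cells(cm: CountMatrix, min_genes: int = 500) -> CountMatrix:
    """Keep the cells detecting at least ``min_genes`` genes.

    A cell expressing strictly fewer than ``min_genes`` genes (count > 0)
    is considered poor quality and removed; a cell at exactly ``min_genes``
    is retained. The gene axis is unchanged and metadata is subset to the
    surviving cells.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    detected = cm.detected_genes_per_cell()
    keep = detected >= min_genes
    if not keep.any():
        raise EmptyResultError(
            f"all {cm.n_cells} cells detect fewer than {min_genes} genes"
        )
    if keep.all():
        return cm
    return cm.subset_cells(keep)


def drop_unexpressed_genes(cm: CountMatrix) -> CountMatrix:
    """Remove genes with zero total count across all cells."""
    totals = np.asarray(cm.counts.sum(axis=1)).ravel()
    keep = totals > 0
    if keep.all():
        return cm
    return cm.subset_genes(keep)


def normalize(cm: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Global-scaling log-normalization.

    value(g, c) = ln(1 + count(g, c) * scale_factor / total_counts(c)).

    Zeros stay zeros, so the result is sparse. Cells with zero total
    count are an error; run :func:`filter_cells` first.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.total_counts_per_cell().astype(float)
    if (totals == 0).any():
        n = int((totals == 0).sum())
        raise ValueError(f"{n} cells have zero total counts; filter cells first")
    X = cm.counts.tocsc().astype(float)
    # scale each column by scale_factor / library size, then log1p in place
    X = X @ sp.diags(scale_factor / totals)
    X = X.tocsr()
    np.log1p(X.data, out=X.data)
    return NormalizedMatrix(
        values=X,
        gene_ids=cm.gene_ids,
        barcodes=cm.barcodes,
        cell_meta=cm.cell_meta,
        scale_factor=scale_factor,
    )


def qc_report(before: CountMatrix, after: CountMatrix) -> pd.DataFrame:
    """Per-sample QC summary: cells before/after filtering and the
    detected-genes and UMI distributions of the retained cells."""
    rows = []
    det_after = pd.Series(after.detected_genes_per_cell(), index=after.barcodes)
    umi_after = pd.Series(after.total_counts_per_cell(), index=after.barcodes)
    for sample, meta in before.cell_meta.groupby("sample_id", sort=True):
        kept = after.cell_meta[after.cell_meta["sample_id"] == sample]
        det = det_after.loc[kept.index]
        umi = umi_after.loc[kept.index]
        rows.append(
            {
                "sample_id": sample,
                "cells_before": len(meta),
                "cells_after": len(kept),
                "median_detected_genes": float(det.median()) if len(det) else np.nan,
                "median_umis": float(umi.median()) if len(umi) else np.nan,
            }
        )
    return pd.DataFrame(rows)
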