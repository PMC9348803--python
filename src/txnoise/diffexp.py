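"""Two-group differential expression with thresholded significance.

Effect sizes are log2 fold changes of back-transformed (linear-scale)
group means of the normalized values, so the 0.26 significance gate
corresponds to a 20% fold difference in averages (log2 1.2 = 0.263).
P-values come from a per-gene two-sided Wilcoxon rank-sum test on the
normalized values, with Benjamini-Hochberg adjustment across the genes
tested in the comparison. A gene is called significant iff its adjusted
p-value is below 0.05 *and* |log2 FC| exceeds 0.26; the effect-size gate
deliberately discards statistically detectable but minuscule shifts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import NormalizedMatrix

__all__ = [
    "LOG2FC_THRESHOLD",
    "P_ADJ_THRESHOLD",
    "log2_fold_change",
    "adjust_bh",
    "de_test",
]

#: |log2 FC| gate for significance: a 20% fold difference in averages
LOG2FC_THRESHOLD = 0.26
P_ADJ_THRESHOLD = 0.05


def _group_arrays(
    nm: NormalizedMatrix, cells_a, cells_b
) -> tuple[np.ndarray, np.ndarray]:
    a = nm.subset_cells(np.asarray(cells_a))
    b = nm.subset_cells(np.asarray(cells_b))
    return (
        np.asarray(a.values.todense(), dtype=float),
        np.asarray(b.values.todense(), dtype=float),
    )


def log2_fold_change(
    nm: NormalizedMatrix,
    cells_a,
    cells_b,
    pseudocount: float = 1e-9,
) -> pd.Series:
    """Per-gene log2 fold change of group A over group B.

    Means are taken on the linear scale (expm1 of the log-normalized
    values) so the ratio reflects average expression, with a small
    pseudocount keeping zero-mean genes finite. Swapping the groups
    negates the result.
    """
    xa, xb = _group_arrays(nm, cells_a, cells_b)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("both groups need at least 2 cells")
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    lfc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    return pd.Series(lfc, index=pd.Index(nm.gene_ids, name="gene"), name="log2fc")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    nm: NormalizedMatrix,
    cells_a,
    cells_b,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    p_adj_threshold: float = P_ADJ_THRESHOLD,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Returns a per-gene frame with ``log2fc`` (A over B), the two-sided
    rank-sum ``p_value``, BH-adjusted ``p_adj`` and the thresholded
    ``significant`` call. A gene constant across both groups pooled gets
    p = 1 by convention. The frame's ``attrs['method']`` records the test
    used.
    """
    xa, xb = _group_arrays(nm, cells_a, cells_b)
    if xa.shape[1] < 3 or xb.shape[1] < 3:
        raise ValueError("both groups need at least 3 cells")
    pooled_constant = (
        np.ptp(np.concatenate([xa, xb], axis=1), axis=1) == 0
    )
    p = np.ones(nm.n_genes)
    todo = ~pooled_constant
    if todo.any():
        res = scipy.stats.mannwhitneyu(
            xa[todo], xb[todo], axis=1, alternative="two-sided", method="asymptotic"
        )
        p[todo] = res.pvalue
    np.clip(p, 0.0, 1.0, out=p)
    lfc = log2_fold_change(nm, cells_a, cells_b)
    p_adj = adjust_bh(p)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": p,
            "p_adj": p_adj,
            "significant": (p_adj < p_adj_threshold)
            & (np.abs(lfc) > log2fc_threshold),
        },
        index=pd.Index(nm.gene_ids, name="gene"),
    )
    out.attrs["method"] = "wilcoxon-ranksum+BH"
    out.attrs["log2fc_threshold"] = log2fc_threshold
    out.attrs["p_adj_threshold"] = p_adj_threshold
    return out
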