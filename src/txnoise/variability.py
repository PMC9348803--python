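"""Transcriptional-noise quantification.

The statistic implemented here measures cell-to-cell transcriptional
variability in three steps:

1. Per-gene mean and squared coefficient of variation (CV^2 =
   variance / mean^2) of log-normalized expression, with the mean-CV^2
   dependence removed by the *distance to median* (DM): the residual of
   log10 CV^2 above a rolling median taken over genes of similar mean.
2. Selection of the top-N genes by DM (highly variable genes, HVGs),
   or use of a fixed user-supplied gene set (e.g. ribosome-biogenesis
   genes) when the question is program-specific.
3. Spearman correlation rho between every pair of selected genes across
   cells, converted to a pairwise distance d = 1 - rho in [0, 2]. The
   distribution of all k(k-1)/2 distances is the noise readout: broader
   or larger distances mean less coherent gene-gene covariation, i.e.
   higher transcriptional noise. Two conditions are compared with a
   two-sample Kolmogorov-Smirnov test on these distributions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import GeneSet, NormalizedMatrix

__all__ = [
    "DistanceDistribution",
    "KSComparison",
    "NoiseReport",
    "compute_gene_stats",
    "distance_to_median",
    "select_hvg",
    "pairwise_distances",
    "compare_distributions",
    "noise_report",
]

#: columns of a gene-stats frame after :func:`compute_gene_stats`
STAT_COLUMNS = ("mean", "cv2", "log10_mean", "log10_cv2")


@dataclass
class DistanceDistribution:
    """The multiset of gene-pair distances for one (group, gene-set) context."""

    distances: np.ndarray
    group: str
    gene_desc: str
    n_genes: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        expected = self.n_genes * (self.n_genes - 1) // 2
        if self.distances.size != expected:
            raise ValueError(
                f"{self.n_genes} genes imply {expected} pair distances, "
                f"got {self.distances.size}"
            )
        if self.distances.size and (
            self.distances.min() < 0 or self.distances.max() > 2
        ):
            raise ValueError("pair distances must lie in [0, 2]")

    def __len__(self) -> int:
        return self.distances.size

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


@dataclass(frozen=True)
class KSComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class NoiseReport:
    """Per-group distance summaries plus all pairwise KS comparisons."""

    groups: pd.DataFrame
    comparisons: pd.DataFrame
    distributions: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene-level statistics
# ---------------------------------------------------------------------------

def compute_gene_stats(nm: NormalizedMatrix) -> pd.DataFrame:
    """Per-gene mean, CV^2 and their log10 transforms across all cells.

    CV^2 uses the unbiased sample variance (ddof=1). Genes whose mean is
    zero across these cells must be excluded beforehand (they have no
    defined CV^2); at least two cells are required. Genes that are
    constant across cells get ``cv2 = 0`` and ``log10_cv2 = -inf``.
    """
    if nm.n_cells < 2:
        raise ValueError("need at least 2 cells to compute a variance")
    X = nm.values
    n = nm.n_cells
    mean = np.asarray(X.mean(axis=1)).ravel()
    if (mean == 0).any():
        k = int((mean == 0).sum())
        raise ValueError(
            f"{k} genes have zero mean in this cell group; drop them first"
        )
    # sparse-friendly sample variance: E[x^2] - mean^2, rescaled to ddof=1
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / (n - 1))
    cv2 = var / mean**2
    with np.errstate(divide="ignore"):
        stats = pd.DataFrame(
            {
                "mean": mean,
                "cv2": cv2,
                "log10_mean": np.log10(mean),
                "log10_cv2": np.log10(cv2),
            },
            index=pd.Index(nm.gene_ids, name="gene"),
        )
    return stats


def distance_to_median(stats: pd.DataFrame, window: int = 51) -> pd.DataFrame:
    """Add the rolling-median baseline and the DM residual to a stats frame.

    Genes are ranked by ``log10_mean`` (ties broken by gene id for
    determinism); the baseline at each rank is the median ``log10_cv2``
    over a ``window``-gene window centred there, truncated at the edges;
    ``dm = log10_cv2 - rolling_median``. The input frame is not modified.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if len(stats) < window:
        raise ValueError(
            f"only {len(stats)} genes but window={window}; use a smaller window"
        )
    # stable sort with a gene-id pre-sort so equal-mean genes rank
    # deterministically
    order = stats.sort_index(kind="mergesort").sort_values(
        "log10_mean", kind="mergesort"
    )
    rolling = (
        order["log10_cv2"]
        .rolling(window, center=True, min_periods=1)
        .median()
    )
    out = stats.copy()
    out["rolling_median"] = rolling.reindex(stats.index)
    out["dm"] = out["log10_cv2"] - out["rolling_median"]
    return out


def select_hvg(stats: pd.DataFrame, n: int = 500, name: str = "hvg") -> GeneSet:
    """The ``n`` genes with the largest DM residual.

    Ties at the cutoff are broken toward the lexicographically smaller
    gene id, so selection is deterministic. Asking for more genes than
    available returns all of them with a warning.
    """
    if "dm" not in stats.columns:
        raise ValueError("stats frame has no 'dm' column; run distance_to_median")
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(stats):
        warnings.warn(
            f"requested {n} HVGs but only {len(stats)} genes available; "
            "returning all",
            stacklevel=2,
        )
        n = len(stats)
    ranked = stats.sort_index(kind="mergesort").sort_values(
        "dm", ascending=False, kind="mergesort"
    )
    return GeneSet(name=name, members=frozenset(ranked.index[:n]))


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def pairwise_distances(
    nm: NormalizedMatrix,
    genes: GeneSet | Sequence[str],
    distance: str = "1-rho",
    group: str = "all",
) -> DistanceDistribution:
    """Spearman-correlation pairwise distances among the given genes.

    For each unordered gene pair, rho is the Spearman correlation of the
    two genes' normalized values across cells (average ranks on ties) and
    the distance is ``1 - rho`` (or ``1 - |rho|`` with
    ``distance="1-abs-rho"``). Genes constant across these cells have no
    defined correlation and are dropped with a warning.
    """
    if distance not in ("1-rho", "1-abs-rho"):
        raise ValueError(f"unknown distance convention {distance!r}")
    if nm.n_cells < 3:
        raise ValueError("need at least 3 cells for rank correlations")
    gene_list = sorted(genes) if isinstance(genes, GeneSet) else list(genes)
    gene_desc = genes.name if isinstance(genes, GeneSet) else f"{len(gene_list)} genes"
    X = nm.dense_rows(gene_list)
    constant = X.std(axis=1) == 0
    if constant.any():
        dropped = [g for g, c in zip(gene_list, constant) if c]
        warnings.warn(
            f"dropping {len(dropped)} constant genes with undefined "
            f"correlations, e.g. {dropped[:3]}",
            stacklevel=2,
        )
        X = X[~constant]
        gene_list = [g for g, c in zip(gene_list, constant) if not c]
    k = len(gene_list)
    if k < 2:
        raise ValueError("need at least 2 non-constant genes for pair distances")
    ranks = scipy.stats.rankdata(X, axis=1)
    rho = np.corrcoef(ranks)
    iu = np.triu_indices(k, 1)
    r = rho[iu]
    d = 1.0 - (np.abs(r) if distance == "1-abs-rho" else r)
    # guard against tiny numerical excursions outside [0, 2]
    np.clip(d, 0.0, 2.0, out=d)
    return DistanceDistribution(
        distances=d, group=group, gene_desc=gene_desc, n_genes=k
    )


def compare_distributions(
    a: DistanceDistribution | np.ndarray,
    b: DistanceDistribution | np.ndarray,
    alternative: str = "two-sided",
) -> KSComparison:
    """Two-sample Kolmogorov-Smirnov comparison of distance distributions.

    Returns the exact supremum ECDF gap D in [0, 1] with the asymptotic
    p-value, plus both sample sizes. ``alternative="greater"`` tests the
    one-sided alternative that sample ``a`` is stochastically larger than
    ``b`` (its ECDF lies below); ``"less"`` the reverse. The p-value treats
    the distances as independent observations; with gene-pair distances the
    effective sample size is smaller, so the sizes are reported for the
    reader to judge.
    """
    xa = a.distances if isinstance(a, DistanceDistribution) else np.asarray(a, float)
    xb = b.distances if isinstance(b, DistanceDistribution) else np.asarray(b, float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("cannot compare empty distributions")
    # scipy's 'greater' refers to the first sample's ECDF being greater,
    # i.e. its values being smaller; flip to the stochastic-order reading
    flip = {"two-sided": "two-sided", "greater": "less", "less": "greater"}
    if alternative not in flip:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = scipy.stats.ks_2samp(xa, xb, alternative=flip[alternative], method="asymp")
    return KSComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=xa.size,
        n_b=xb.size,
    )


# ---------------------------------------------------------------------------
# grouped report
# ---------------------------------------------------------------------------

def noise_report(
    nm: NormalizedMatrix,
    groups: Mapping[str, np.ndarray],
    gene_set: GeneSet | None = None,
    hvg_n: int = 500,
    window: int = 51,
    distance: str = "1-rho",
    min_cells: int = 3,
) -> NoiseReport:
    """Noise distributions per cell group and KS comparisons between them.

    ``groups`` maps a label to a boolean mask (or index array) over cells.
    Gene-selection policy: with ``gene_set=None`` each group gets its own
    top-``hvg_n`` HVGs by DM computed within that group; with a fixed
    ``gene_set`` the same genes (those expressed in the group) are used
    everywhere and DM plays no role. Groups with fewer than ``min_cells``
    cells are excluded with a warning. The first group (mapping order) is
    the reference for the ``D_vs_reference`` column.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    dists: dict[str, DistanceDistribution] = {}
    for label, mask in groups.items():
        sub = nm.subset_cells(np.asarray(mask))
        if sub.n_cells < min_cells:
            warnings.warn(
                f"group {label!r} has {sub.n_cells} cells (<{min_cells}); excluded",
                stacklevel=2,
            )
            continue
        expressed = np.asarray(sub.values.sum(axis=1)).ravel() > 0
        sub = sub.subset_genes(expressed)
        if gene_set is None:
            stats = compute_gene_stats(sub)
            stats = distance_to_median(stats, window=window)
            genes: GeneSet = select_hvg(stats, n=hvg_n, name=f"hvg:{label}")
        else:
            present = frozenset(gene_set.members) & set(sub.gene_ids)
            if len(present) < 2:
                warnings.warn(
                    f"gene set {gene_set.name!r} has <2 genes expressed in "
                    f"group {label!r}; excluded",
                    stacklevel=2,
                )
                continue
            genes = GeneSet(name=gene_set.name, members=present)
        dists[label] = pairwise_distances(sub, genes, distance=distance, group=label)
    if len(dists) < 2:
        raise ValueError("fewer than 2 usable groups after exclusions")

    labels = list(dists)
    ref = labels[0]
    group_rows = []
    for label in labels:
        dd = dists[label]
        if label == ref:
            d_ref, p_ref = 0.0, 1.0
        else:
            ks = compare_distributions(dists[label], dists[ref])
            d_ref, p_ref = ks.statistic, ks.p_value
        group_rows.append(
            {
                "group": label,
                "n_genes": dd.n_genes,
                "n_pairs": len(dd),
                "median_distance": dd.median,
                "D_vs_reference": d_ref,
                "p_vs_reference": p_ref,
            }
        )
    comp_rows = []
    for la, lb in itertools.combinations(labels, 2):
        ks = compare_distributions(dists[la], dists[lb])
        comp_rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "ks_statistic": ks.statistic,
                "p_value": ks.p_value,
                "median_a": dists[la].median,
                "median_b": dists[lb].median,
            }
        )
    return NoiseReport(
        groups=pd.DataFrame(group_rows),
        comparisons=pd.DataFrame(comp_rows),
        distributions=dists,
    )
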