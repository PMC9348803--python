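"""Marker-rule classification of hematopoietic progenitor states.

Cells are assigned to one of five progenitor compartments observed in
RUNX1-RUNX1T1(9a) preleukemia by combinatorial marker-gene detection:

* **LMPP** lymphoid-myeloid primed progenitor: Ly6e+ Cd34+ Flt3+,
  Cd79a- Cd14- (supporting TFs Gata2, Myb)
* **GMP** granulocyte-monocyte progenitor: Ly6e+ Cd34+ Fcgr3+, Flt3-
  Cd79a- Cd14- (supporting Cebpa)
* **BAP** B-cell-affiliated progenitor: Ly6e+ Cd79a+, Cd34- Flt3- Cd14-
  Fcgr3- (supporting Cd19, Il7r, Ebf1)
* **MAP** monocyte/macrophage-affiliated progenitor: Ly6e+ Cd14+ Fcgr3+,
  Cd34- Flt3- Cd79a- (supporting Mafb)
* **PLP** preleukemia progenitor: Ly6e-low/negative and Cd34-negative
  with variable Fcgr3/Cd14 and occasional Cd48. Encoded here with
  Fcgr3/Cd14 as its detected markers and Ly6e/Cd34 in the negative set;
  Cd48 is a low-weight supporting marker that separates PLP from MAP.

Scoring is a reproducible surrogate for manual annotation: each rule
scores +1 per detected positive marker, -1 per detected negative marker
and +aux_weight (default 0.5) per detected supporting marker, where
"detected" means normalized expression above ``tau`` (default 0, i.e.
any observed UMI). A cell takes the label of the uniquely best-scoring
rule when that score reaches the assignment floor; ties or sub-floor
maxima leave the cell unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .io_core import GeneSet, NormalizedMatrix

__all__ = [
    "MarkerRule",
    "TTestResult",
    "COMPARTMENTS",
    "UNASSIGNED",
    "MARKER_ALIASES",
    "default_rules",
    "load_rules",
    "save_rules",
    "score_cells",
    "classify_cells",
    "compartment_proportions",
    "signature_score",
    "compare_signature_levels",
]

COMPARTMENTS = ("LMPP", "GMP", "BAP", "MAP", "PLP")
UNASSIGNED = "unassigned"

#: protein/antigen names occasionally used for the same markers; rule files
#: may use either spelling and are canonicalized on load.
MARKER_ALIASES = {
    "Sca1": "Ly6e",
    "Sca-1": "Ly6e",
    "CD34": "Cd34",
    "FcgR": "Fcgr3",
    "Fcgr": "Fcgr3",
    "CD16/32": "Fcgr3",
    "CD14": "Cd14",
    "CD79a": "Cd79a",
    "CD19": "Cd19",
    "Ebf": "Ebf1",
    "CD48": "Cd48",
    "Il7ra": "Il7r",
}


@dataclass(frozen=True)
class MarkerRule:
    """Positive/negative/supporting marker genes defining one compartment."""

    compartment: str
    positive: frozenset = field(default_factory=frozenset)
    negative: frozenset = field(default_factory=frozenset)
    aux_positive: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        object.__setattr__(self, "aux_positive", frozenset(self.aux_positive))
        if self.positive & self.negative:
            raise ValueError(
                f"{self.compartment}: genes {sorted(self.positive & self.negative)} "
                "are both positive and negative"
            )

    @property
    def genes(self) -> frozenset:
        return self.positive | self.negative | self.aux_positive


def default_rules() -> list[MarkerRule]:
    """The five default progenitor rules described in the module docstring."""
    return [
        MarkerRule(
            "LMPP",
            positive={"Ly6e", "Cd34", "Flt3"},
            negative={"Cd79a", "Cd14"},
            aux_positive={"Gata2", "Myb"},
        ),
        MarkerRule(
            "GMP",
            positive={"Ly6e", "Cd34", "Fcgr3"},
            negative={"Flt3", "Cd79a", "Cd14"},
            aux_positive={"Cebpa"},
        ),
        MarkerRule(
            "BAP",
            positive={"Ly6e", "Cd79a"},
            negative={"Cd34", "Flt3", "Cd14", "Fcgr3"},
            aux_positive={"Cd19", "Il7r", "Ebf1"},
        ),
        MarkerRule(
            "MAP",
            positive={"Ly6e", "Cd14", "Fcgr3"},
            negative={"Cd34", "Flt3", "Cd79a"},
            aux_positive={"Mafb"},
        ),
        MarkerRule(
            "PLP",
            positive={"Fcgr3", "Cd14"},
            negative={"Ly6e", "Cd34"},
            aux_positive={"Cd48"},
        ),
    ]


def _canon(symbols: Sequence[str]) -> frozenset:
    return frozenset(MARKER_ALIASES.get(s, s) for s in symbols)


def load_rules(path) -> list[MarkerRule]:
    """Load marker rules from a YAML document.

    Format: a mapping of compartment name to ``{positive: [...],
    negative: [...], aux_positive: [...]}``. Marker aliases (e.g. Sca1,
    FcgR) are canonicalized to gene symbols.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping) or not doc:
        raise ValueError(f"rules file {path} must map compartments to marker lists")
    rules = []
    for comp, spec in doc.items():
        spec = spec or {}
        rules.append(
            MarkerRule(
                compartment=str(comp),
                positive=_canon(spec.get("positive", [])),
                negative=_canon(spec.get("negative", [])),
                aux_positive=_canon(spec.get("aux_positive", [])),
            )
        )
    return rules


def save_rules(rules: Sequence[MarkerRule], path) -> None:
    doc = {
        r.compartment: {
            "positive": sorted(r.positive),
            "negative": sorted(r.negative),
            "aux_positive": sorted(r.aux_positive),
        }
        for r in rules
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------

def score_cells(
    nm: NormalizedMatrix,
    rules: Sequence[MarkerRule] | None = None,
    tau: float = 0.0,
    aux_weight: float = 0.5,
) -> pd.DataFrame:
    """Score every cell against every rule; returns cells x compartments.

    Rule genes absent from the matrix are dropped with a warning; a rule
    with no remaining genes is an error.
    """
    rules = list(default_rules() if rules is None else rules)
    available = set(nm.gene_ids)
    scores = np.zeros((nm.n_cells, len(rules)))
    for j, rule in enumerate(rules):
        missing = rule.genes - available
        if missing:
            warnings.warn(
                f"rule {rule.compartment}: genes {sorted(missing)} absent from "
                "matrix; dropped",
                stacklevel=2,
            )
        pos = sorted(rule.positive & available)
        neg = sorted(rule.negative & available)
        aux = sorted(rule.aux_positive & available)
        if not (pos or neg or aux):
            raise ValueError(
                f"rule {rule.compartment} has no genes present in the matrix"
            )
        for genes, weight in ((pos, 1.0), (neg, -1.0), (aux, aux_weight)):
            if genes:
                detected = nm.dense_rows(genes) > tau
                scores[:, j] += weight * detected.sum(axis=0)
    return pd.DataFrame(
        scores,
        index=pd.Index(nm.barcodes, name="barcode"),
        columns=[r.compartment for r in rules],
    )


def classify_cells(
    nm: NormalizedMatrix,
    rules: Sequence[MarkerRule] | None = None,
    floor: float = 1.0,
    tau: float = 0.0,
    aux_weight: float = 0.5,
) -> pd.DataFrame:
    """Assign each cell the label of its uniquely best-scoring rule.

    A cell is labelled with the argmax compartment when that maximum is
    unique and at least ``floor``; a tied maximum or one below the floor
    leaves the cell ``unassigned``. Returns a frame indexed by barcode
    with a ``label`` column and one ``score_<compartment>`` column per
    rule.
    """
    scores = score_cells(nm, rules=rules, tau=tau, aux_weight=aux_weight)
    arr = scores.to_numpy()
    best = arr.max(axis=1)
    n_at_max = (arr == best[:, None]).sum(axis=1)
    argmax = arr.argmax(axis=1)
    labels = np.where(
        (best >= floor) & (n_at_max == 1),
        scores.columns.to_numpy()[argmax],
        UNASSIGNED,
    )
    out = pd.DataFrame({"label": labels}, index=scores.index)
    for comp in scores.columns:
        out[f"score_{comp}"] = scores[comp]
    return out


def compartment_proportions(
    calls: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group compartment fractions (groups x labels, rows sum to 1).

    ``groups`` maps barcode to a group key (e.g. the ``sample_id``
    metadata column); with ``None`` all cells form a single ``all`` group.
    Unassigned cells are reported as their own category.
    """
    labels = calls["label"]
    if groups is None:
        groups = pd.Series("all", index=labels.index)
    groups = groups.reindex(labels.index)
    if groups.isna().any():
        raise ValueError("every cell needs a group key")
    tab = pd.crosstab(groups, labels)
    if (tab.sum(axis=1) == 0).any():
        raise ValueError("every group must contain at least one cell")
    frac = tab.div(tab.sum(axis=1), axis=0)
    # stable column order: known compartments first, then extras
    cols = [c for c in (*COMPARTMENTS, UNASSIGNED) if c in frac.columns]
    cols += [c for c in frac.columns if c not in cols]
    frac = frac[cols]
    frac.index.name = "group"
    frac.columns.name = "label"
    return frac


# ---------------------------------------------------------------------------
# gene signatures
# ---------------------------------------------------------------------------

def signature_score(nm: NormalizedMatrix, gs: GeneSet) -> pd.Series:
    """Per-cell mean normalized expression over the signature's genes.

    Genes absent from the matrix are dropped with a warning; at least one
    must be present. Duplicates are impossible by GeneSet construction.
    """
    present = sorted(set(gs.members) & set(nm.gene_ids))
    missing = set(gs.members) - set(present)
    if missing:
        warnings.warn(
            f"signature {gs.name!r}: {len(missing)} genes absent from matrix",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"no genes of signature {gs.name!r} present in matrix")
    block = nm.dense_rows(present)
    return pd.Series(
        block.mean(axis=0), index=pd.Index(nm.barcodes, name="barcode"), name=gs.name
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_signature_levels(
    scores_a: np.ndarray | pd.Series, scores_b: np.ndarray | pd.Series
) -> TTestResult:
    """Welch two-sample t-test (two-sided) on per-cell signature scores.

    Degenerate case: both groups have zero variance. Equal means then give
    t = 0, p = 1; different means give an infinite statistic with p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, a.size, b.size)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * np.inf, 0.0, a.size, b.size)
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue), a.size, b.size)
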