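"""Synthetic UMI-count datasets with known generative structure.

The generator emulates a 10x-style preleukemia progenitor experiment:
four samples (two genotypes x two timepoints) of a few hundred cells
each, five latent progenitor compartments distinguished by elevated
marker-gene expression, and a designated "noise module" of co-regulated
genes (a ribosome-biogenesis-like program) whose behaviour differs by
genotype.

Counts follow a hierarchical negative-binomial model. Each gene has a
baseline relative abundance; a cell's expected count vector is its
library size times the compartment- and genotype-adjusted abundances,
renormalized per cell. Gene-level overdispersion is Gamma-Poisson with
per-gene inverse-dispersion theta. The module is organised into
``n_subprograms`` co-regulated sub-programs; each sub-program has a
bounded per-cell activity factor (mean 1, variance ``program_cv2``) that
its genes follow fully, while every other non-marker gene follows one
factor with a heterogeneous, mostly weak loading (a graded
growth/cell-state component). The factors make program genes positively
covary, which is what the pairwise-distance statistic reads as coherent
transcription. In NULL cells the module's *independent* dispersion
component is inflated (theta divided by ``dispersion_multiplier`` f >= 1)
and its mean optionally down-shifted (``mean_multiplier`` m <= 1); extra
gene-autonomous noise dilutes the shared-factor correlations, so pairwise
distances involving module genes rise — the generative analogue of
program decoherence upon loss of a noise-restraining factor. Many small
sub-programs with bounded, low-kurtosis factors keep the *realized*
factor statistics of a few hundred cells stable, so two same-law cell
groups produce closely matching distance distributions.

Every dataset carries a :class:`SimTruth` with per-cell compartment
labels and per-gene generative parameters for recovery tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_core import CountMatrix, GeneSet, write_mtx

__all__ = [
    "CompartmentSpec",
    "SampleSpec",
    "NoiseModuleSpec",
    "SimConfig",
    "SimTruth",
    "TruthReport",
    "default_config",
    "simulate_dataset",
    "truth_report",
    "write_simulation",
]


@dataclass
class CompartmentSpec:
    """One latent cell state: its frequency and elevated marker genes."""

    label: str
    proportion: float
    #: gene symbol -> mean multiplier applied in this compartment
    markers: dict = field(default_factory=dict)


@dataclass
class SampleSpec:
    sample_id: str
    genotype: str
    timepoint: str
    n_cells: int
    #: optional per-sample compartment-proportion overrides
    proportions: dict | None = None


@dataclass
class NoiseModuleSpec:
    """The designated co-regulated gene module and its genotype effects."""

    genes: tuple
    #: f >= 1; NULL cells draw module counts with theta / f
    dispersion_multiplier: float = 2.0
    #: 0 < m <= 1; NULL cells' module means are scaled by m
    mean_multiplier: float = 1.0
    #: squared CV of each per-cell program-activity factor; factors are
    #: bounded (scaled Beta on [0, 2], mean 1), so program_cv2 < 1/3 maps
    #: to a unimodal factor and 1/3 to a uniform one
    program_cv2: float = 1.0 / 3.0
    #: number of independently fluctuating sub-programs within the module
    #: (genes are split round-robin; each sub-program has its own factor)
    n_subprograms: int = 6
    #: upper scale of per-gene coupling of non-module genes to the program
    #: factors. Each non-module gene gets loading w = background_coupling x
    #: Beta(0.5, 2.5) on one factor — a heterogeneous growth/cell-state
    #: component, mostly weak with a tail of strongly coupled genes.
    #: 0 disables the coupling entirely.
    background_coupling: float = 0.9
    #: approximate expected counts per module gene at median depth
    mean_expected: float = 5.0
    #: baseline inverse-dispersion of module genes (WT)
    module_theta: float = 3.0


@dataclass
class SimConfig:
    """Full generative specification of one synthetic dataset."""

    n_genes: int
    compartments: list
    samples: list
    noise_module: NoiseModuleSpec
    #: log-normal parameters of background relative abundances
    mean_log_mu: float = 0.0
    mean_log_sigma: float = 1.35
    #: median per-gene inverse-dispersion and its log-normal jitter
    theta: float = 3.0
    theta_log_sigma: float = 0.25
    #: approximate expected off-compartment counts of a marker gene
    marker_baseline_expected: float = 0.06
    #: per-cell library sizes are log-normal with this median / log-sd
    library_median: float = 5900.0
    library_log_sigma: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        labels = [c.label for c in self.compartments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate compartment labels")
        base = {c.label: c.proportion for c in self.compartments}
        if abs(sum(base.values()) - 1.0) > 1e-9:
            raise ValueError("compartment proportions must sum to 1")
        for s in self.samples:
            props = s.proportions or base
            if set(props) != set(base):
                raise ValueError(
                    f"sample {s.sample_id}: proportion overrides must cover "
                    "every compartment"
                )
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {s.sample_id}: proportions must sum to 1"
                )
            if s.n_cells <= 0:
                raise ValueError("samples need at least one cell")
        m = self.noise_module
        if m.dispersion_multiplier < 1:
            raise ValueError("dispersion_multiplier must be >= 1")
        if not (0 < m.mean_multiplier <= 1):
            raise ValueError("mean_multiplier must be in (0, 1]")
        if not (0 <= m.program_cv2 <= 1.0 / 3.0 + 1e-12):
            raise ValueError("program_cv2 must lie in [0, 1/3] (bounded factors)")
        if not (0 <= m.background_coupling < 1):
            raise ValueError("background_coupling must lie in [0, 1)")
        if m.module_theta <= 0:
            raise ValueError("module_theta must be positive")
        if m.n_subprograms < 1 or m.n_subprograms > max(1, len(m.genes)):
            raise ValueError("n_subprograms must be in [1, n module genes]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        marker_genes = {g for c in self.compartments for g in c.markers}
        n_special = len(marker_genes | set(m.genes))
        if self.n_genes < n_special + 10:
            raise ValueError("n_genes too small for markers + module")

    # -- (de)serialization for config files ----------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_module"]["genes"] = list(self.noise_module.genes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["compartments"] = [CompartmentSpec(**c) for c in d["compartments"]]
        d["samples"] = [SampleSpec(**s) for s in d["samples"]]
        nm = dict(d["noise_module"])
        nm["genes"] = tuple(nm["genes"])
        d["noise_module"] = NoiseModuleSpec(**nm)
        return cls(**d)


def default_config(seed: int = 0) -> SimConfig:
    """The default study design: four samples at the observed per-sample
    cell counts, five marker-defined compartments, and a 150-gene
    co-regulated module that is noisier (f = 2) and slightly
    down-shifted (m = 0.8) in NULL cells."""
    mult = 100.0
    compartments = [
        CompartmentSpec(
            "LMPP", 0.30, {g: mult for g in ("Ly6e", "Cd34", "Flt3", "Gata2", "Myb")}
        ),
        CompartmentSpec(
            "GMP", 0.30, {g: mult for g in ("Ly6e", "Cd34", "Fcgr3", "Cebpa")}
        ),
        CompartmentSpec(
            "BAP", 0.10, {g: mult for g in ("Ly6e", "Cd79a", "Cd19", "Il7r", "Ebf1")}
        ),
        CompartmentSpec(
            "MAP", 0.10, {g: mult for g in ("Ly6e", "Cd14", "Fcgr3", "Mafb")}
        ),
        CompartmentSpec("PLP", 0.20, {g: mult for g in ("Fcgr3", "Cd14", "Cd48")}),
    ]
    samples = [
        SampleSpec("WT_2mo", "WT", "2mo", 379),
        SampleSpec("NULL_2mo", "NULL", "2mo", 369),
        SampleSpec("WT_4mo", "WT", "4mo", 518),
        SampleSpec("NULL_4mo", "NULL", "4mo", 501),
    ]
    module = NoiseModuleSpec(
        genes=tuple(f"Rbg{i:03d}" for i in range(1, 151)),
        dispersion_multiplier=2.0,
        mean_multiplier=0.8,
    )
    return SimConfig(
        n_genes=3000,
        compartments=compartments,
        samples=samples,
        noise_module=module,
        seed=seed,
    )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``cell_table`` carries each cell's sample and true compartment;
    ``gene_table`` each gene's module membership, marker role, baseline
    relative abundance and theta; ``rel_expression`` the per-cell
    expected count fraction for every (genotype, compartment) condition.
    """

    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    rel_expression: pd.DataFrame
    config: SimConfig

    @property
    def module_genes(self) -> GeneSet:
        return GeneSet("noise_module", frozenset(self.config.noise_module.genes))


def _gene_list(cfg: SimConfig) -> tuple[list, dict]:
    marker_of: dict[str, str] = {}
    markers: list[str] = []
    for comp in cfg.compartments:
        for g in comp.markers:
            if g not in marker_of:
                marker_of[g] = comp.label
                markers.append(g)
            else:
                marker_of[g] += f"+{comp.label}"
    module = [g for g in cfg.noise_module.genes if g not in marker_of]
    if len(module) != len(cfg.noise_module.genes):
        raise ValueError("module genes may not double as compartment markers")
    n_background = cfg.n_genes - len(markers) - len(module)
    background = [f"G{i:04d}" for i in range(1, n_background + 1)]
    taken = set(markers) | set(module)
    background = [g for g in background if g not in taken]
    i = n_background
    while len(background) < n_background:
        i += 1
        g = f"G{i:04d}"
        if g not in taken:
            background.append(g)
    return markers + module + background, marker_of


def simulate_dataset(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw one dataset from the generative model; reproducible from seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, marker_of = _gene_list(cfg)
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    module_idx = np.array([gene_idx[g] for g in cfg.noise_module.genes], dtype=int)
    is_module = np.zeros(n_genes, dtype=bool)
    is_module[module_idx] = True

    # baseline relative abundances
    w = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, size=n_genes)
    bg_mask = np.ones(n_genes, dtype=bool)
    for g in marker_of:
        bg_mask[gene_idx[g]] = False
    bg_mask[module_idx] = False
    sum_bg = w[bg_mask].sum()
    # express marker / module abundances in approximate expected counts at
    # the median library size
    per_count = sum_bg / cfg.library_median
    for g in marker_of:
        w[gene_idx[g]] = cfg.marker_baseline_expected * per_count
    w[module_idx] = (
        cfg.noise_module.mean_expected
        * per_count
        * rng.lognormal(-0.03, 0.25, size=module_idx.size)
    )

    theta = cfg.theta * rng.lognormal(0.0, cfg.theta_log_sigma, size=n_genes)
    theta[module_idx] = cfg.noise_module.module_theta

    # per-compartment x genotype adjusted abundance fractions
    comp_labels = [c.label for c in cfg.compartments]
    rel_cols = {}
    for comp in cfg.compartments:
        w_comp = w.copy()
        for g, mult in comp.markers.items():
            w_comp[gene_idx[g]] *= mult
        for genotype in ("WT", "NULL"):
            w_gt = w_comp.copy()
            if genotype == "NULL":
                w_gt[module_idx] *= cfg.noise_module.mean_multiplier
            rel_cols[(genotype, comp.label)] = w_gt / w_gt.sum()
    rel = pd.DataFrame(rel_cols, index=pd.Index(genes, name="gene"))
    rel.columns = pd.MultiIndex.from_tuples(rel.columns, names=["genotype", "compartment"])

    # bounded program-activity factors: 2 * Beta(a, a) has mean 1, support
    # [0, 2] and CV^2 = 1/(2a+1); low kurtosis keeps the factors' sample
    # statistics stable across replicates
    pcv2 = cfg.noise_module.program_cv2
    beta_a = (1.0 / pcv2 - 1.0) / 2.0 if pcv2 > 0 else None
    n_sub = cfg.noise_module.n_subprograms
    # every gene listens to one sub-program. Module genes couple fully
    # (loading 1); other non-marker genes get a heterogeneous, mostly-weak
    # loading — a graded growth/cell-state component. Marker genes stay
    # uncoupled so compartment identity is orthogonal to program activity.
    gene_block = np.arange(n_genes) % n_sub
    gene_block[module_idx] = np.arange(module_idx.size) % n_sub
    loading = cfg.noise_module.background_coupling * rng.beta(0.5, 2.5, size=n_genes)
    for g in marker_of:
        loading[gene_idx[g]] = 0.0
    loading[module_idx] = 1.0
    f = cfg.noise_module.dispersion_multiplier
    base_props = {c.label: c.proportion for c in cfg.compartments}

    blocks, barcodes, meta_rows, labels_all = [], [], [], []
    for s in cfg.samples:
        props = s.proportions or base_props
        p_vec = np.array([props[l] for l in comp_labels])
        labels = rng.choice(len(comp_labels), size=s.n_cells, p=p_vec)
        lib = rng.lognormal(np.log(cfg.library_median), cfg.library_log_sigma, s.n_cells)
        # expected counts per gene per cell
        frac = np.stack(
            [rel[(s.genotype, comp_labels[k])].to_numpy() for k in labels], axis=1
        )
        lam = frac * lib[None, :]
        if beta_a is not None and module_idx.size:
            activity = 2.0 * rng.beta(beta_a, beta_a, size=(n_sub, s.n_cells))
            lam = lam * (1.0 + loading[:, None] * (activity[gene_block, :] - 1.0))
        th = np.repeat(theta[:, None], s.n_cells, axis=1)
        if s.genotype == "NULL" and f > 1:
            th[module_idx, :] /= f
        rate = rng.gamma(shape=th, scale=lam / th)
        counts = rng.poisson(rate)
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
        bc = [f"{s.sample_id}:c{i + 1:04d}" for i in range(s.n_cells)]
        barcodes.extend(bc)
        labels_all.extend(comp_labels[k] for k in labels)
        meta_rows.extend(
            {
                "barcode": b,
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "timepoint": s.timepoint,
            }
            for b in bc
        )

    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows).set_index("barcode")
    cm = CountMatrix(
        counts=counts,
        gene_ids=np.array(genes, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )
    cell_table = meta.copy()
    cell_table["compartment"] = labels_all
    gene_table = pd.DataFrame(
        {
            "in_module": is_module,
            "subprogram": np.where(loading > 0, gene_block, -1),
            "program_loading": loading,
            "marker_of": [marker_of.get(g, "") for g in genes],
            "theta": theta,
            "rel_abundance": w / w.sum(),
        },
        index=pd.Index(genes, name="gene"),
    )
    truth = SimTruth(
        cell_table=cell_table, gene_table=gene_table, rel_expression=rel, config=cfg
    )
    return cm, truth


@dataclass
class TruthReport:
    compartment_counts: pd.DataFrame
    module_effects: pd.DataFrame


def truth_report(truth: SimTruth) -> TruthReport:
    """Summaries for joining against pipeline outputs in recovery tests:
    per-sample compartment counts and per-genotype module effect sizes."""
    counts = pd.crosstab(
        truth.cell_table["sample_id"], truth.cell_table["compartment"]
    )
    cfg = truth.config
    module = truth.gene_table[truth.gene_table["in_module"]]
    rows = []
    for genotype in ("WT", "NULL"):
        f = cfg.noise_module.dispersion_multiplier if genotype == "NULL" else 1.0
        m = cfg.noise_module.mean_multiplier if genotype == "NULL" else 1.0
        rows.append(
            {
                "genotype": genotype,
                "n_module_genes": len(module),
                "dispersion_multiplier": f,
                "mean_multiplier": m,
                "mean_theta": float((module["theta"] / f).mean()),
                "program_cv2": cfg.noise_module.program_cv2,
            }
        )
    return TruthReport(
        compartment_counts=counts, module_effects=pd.DataFrame(rows)
    )


def write_simulation(cm: CountMatrix, truth: SimTruth, out_dir) -> dict:
    """Write the MTX bundle plus ``truth.tsv``, ``module_genes.txt`` and the
    resolved config (with seed) for provenance."""
    out = Path(out_dir)
    paths = write_mtx(cm, out)
    truth_path = out / "truth.tsv"
    truth.cell_table.to_csv(truth_path, sep="\t", index_label="barcode")
    module_path = out / "module_genes.txt"
    module_path.write_text("\n".join(truth.config.noise_module.genes) + "\n")
    cfg_path = out / "sim_config.yaml"
    cfg_path.write_text(yaml.safe_dump(truth.config.to_dict(), sort_keys=False))
    paths.update(truth=truth_path, module_genes=module_path, config=cfg_path)
    return paths
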