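"""End-to-end orchestration: input -> QC -> classify -> noise -> DE.

A single YAML (or dict) configuration drives the run; every stage's
parameters live in its own block and all randomness derives from one
seed, so a finished run is reproducible byte-for-byte. A structured
manifest records the package version, the configuration hash, the seed
and per-stage dimensions plus checksums of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version

try:
    _version = _pkg_version("txnoise")
except Exception:  # pragma: no cover
    _version = "unknown"

from .compartments import classify_cells, compartment_proportions, load_rules
from .diffexp import de_test
from .io_core import CountMatrix, load_gene_set, read_mtx_dir
from .preprocess import drop_unexpressed_genes, filter_cells, normalize, qc_report
from .simulate import SimConfig, default_config, simulate_dataset, write_simulation
from .variability import noise_report

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("txnoise")

REQUIRED_BLOCKS = ("input", "preprocess", "classify", "variability", "diffexp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    if not isinstance(cfg, Mapping):
        raise PipelineError("config: not a mapping")
    missing = [b for b in REQUIRED_BLOCKS if b not in cfg]
    if missing:
        raise PipelineError(f"config: missing required stage blocks {missing}")
    if "out_dir" not in cfg:
        raise PipelineError("config: missing out_dir")
    return dict(cfg)


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def run_pipeline(config, out_dir=None) -> Path:
    """Run all stages; returns the output directory.

    ``config`` is a YAML path or a dict with blocks ``input``,
    ``preprocess``, ``classify``, ``variability``, ``diffexp`` and a
    top-level ``out_dir`` and ``seed``. Outputs: ``qc_report.tsv``,
    ``calls.tsv``, ``proportions.tsv``, ``noise_groups.tsv``,
    ``noise_comparisons.tsv``, ``de.tsv`` and ``manifest.json`` (plus the
    simulated dataset when the input is a simulation).
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "package": "txnoise",
        "version": _version,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }

    try:
        # ------------------------------------------------------ input
        stage = "input"
        block = cfg["input"]
        kind = block.get("kind")
        truth = None
        if kind == "simulate":
            sim_cfg = block.get("config")
            if sim_cfg is None:
                sc = default_config(seed=seed)
            else:
                sim_cfg = dict(sim_cfg)
                sim_cfg.setdefault("seed", seed)
                sc = SimConfig.from_dict(sim_cfg)
            cm, truth = simulate_dataset(sc)
            write_simulation(cm, truth, out / "simulated")
        elif kind == "mtx":
            cm = read_mtx_dir(block["dir"])
        else:
            raise PipelineError(f"input: unknown kind {kind!r}")
        logger.info("input: %d genes x %d cells", cm.n_genes, cm.n_cells)
        manifest["stages"]["input"] = {"n_genes": cm.n_genes, "n_cells": cm.n_cells}

        # ------------------------------------------------- preprocess
        stage = "preprocess"
        block = cfg["preprocess"]
        filtered = filter_cells(cm, min_genes=int(block.get("min_genes", 500)))
        filtered = drop_unexpressed_genes(filtered)
        nm = normalize(filtered, scale_factor=float(block.get("scale_factor", 10_000)))
        _write_tsv(qc_report(cm, filtered), out / "qc_report.tsv", index=False)
        logger.info(
            "preprocess: %d/%d cells retained, %d genes expressed",
            filtered.n_cells,
            cm.n_cells,
            filtered.n_genes,
        )
        manifest["stages"]["preprocess"] = {
            "cells_before": cm.n_cells,
            "cells_after": filtered.n_cells,
            "genes_after": filtered.n_genes,
        }

        # --------------------------------------------------- classify
        stage = "classify"
        block = cfg["classify"]
        rules = load_rules(block["rules"]) if block.get("rules") else None
        calls = classify_cells(
            nm,
            rules=rules,
            floor=float(block.get("floor", 1.0)),
            tau=float(block.get("tau", 0.0)),
            aux_weight=float(block.get("aux_weight", 0.5)),
        )
        props = compartment_proportions(calls, groups=nm.cell_meta["sample_id"])
        _write_tsv(calls, out / "calls.tsv")
        _write_tsv(props, out / "proportions.tsv")
        manifest["stages"]["classify"] = {
            "n_cells": len(calls),
            "n_unassigned": int((calls["label"] == "unassigned").sum()),
        }

        # ------------------------------------------------ variability
        stage = "variability"
        block = cfg["variability"]
        group_by = block.get("group_by", "genotype")
        group_cols = [c.strip() for c in group_by.split(",")]
        meta = nm.cell_meta.copy()
        meta["compartment"] = calls["label"]
        key = meta[group_cols].astype(str).agg("/".join, axis=1)
        groups = {
            label: (key == label).to_numpy() for label in sorted(key.unique())
        }
        gene_set = None
        if block.get("gene_set"):
            gene_set = load_gene_set(block["gene_set"])
        report = noise_report(
            nm,
            groups,
            gene_set=gene_set,
            hvg_n=int(block.get("hvg_n", 500)),
            window=int(block.get("window", 51)),
            distance=block.get("distance", "1-rho"),
        )
        _write_tsv(report.groups, out / "noise_groups.tsv", index=False)
        _write_tsv(report.comparisons, out / "noise_comparisons.tsv", index=False)
        manifest["stages"]["variability"] = {
            "groups": list(report.distributions),
            "n_pairs": {k: len(v) for k, v in report.distributions.items()},
        }

        # ---------------------------------------------------- diffexp
        stage = "diffexp"
        block = cfg["diffexp"]
        query_a = block.get("group_a", "genotype == 'NULL'")
        query_b = block.get("group_b", "genotype == 'WT'")
        mask_a = meta.eval(query_a).to_numpy()
        mask_b = meta.eval(query_b).to_numpy()
        de = de_test(nm, mask_a, mask_b)
        _write_tsv(de, out / "de.tsv")
        manifest["stages"]["diffexp"] = {
            "n_a": int(mask_a.sum()),
            "n_b": int(mask_b.sum()),
            "n_significant": int(de["significant"].sum()),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
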