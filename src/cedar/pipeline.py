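"""End-to-end orchestration: baseline test -> tree -> priors -> posteriors.

`run_cedar` is the in-memory entry point; `run_pipeline` wraps it with
file I/O, artifact writing, and a provenance record.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .estimation import (
    BaselineTestResult,
    PriorEstimate,
    TreeTopology,
    baseline_test,
    estimate_node_priors,
    estimate_tree,
    single_layer_topology,
)
from .inference import (
    DEFAULT_POSTERIOR_CUTOFF,
    PosteriorTable,
    call_features,
    compute_posteriors,
)
from .io import read_bulk, read_design, read_proportions, read_tree, write_table, write_tree
from .model import BulkMatrix, DesignSpec, ProportionMatrix, fit_all_states
from .tree import CellTypeTree

logger = logging.getLogger(__name__)

__all__ = ["Mode", "CedarResult", "RunConfig", "run_cedar", "run_pipeline", "topology_of"]

Mode = Literal["cedar-s", "cedar-m", "baseline"]


def topology_of(tree: CellTypeTree) -> TreeTopology:
    """Strip a tree down to its topology (for re-estimating priors on it)."""
    return TreeTopology(
        parent_map={n: nd.parent for n, nd in tree.nodes.items()},
        leaf_labels=list(tree.leaf_labels),
    )


@dataclass
class CedarResult:
    """Everything one analysis produces."""

    mode: str
    baseline: BaselineTestResult
    tree: CellTypeTree | None
    priors: PriorEstimate | None
    posteriors: PosteriorTable | None
    global_fdr: dict[str, float | None] | None


def _align_proportions(theta: ProportionMatrix, tree: CellTypeTree) -> ProportionMatrix:
    if set(theta.cell_types) != set(tree.leaf_labels):
        raise ValueError(
            "cell types in the proportion matrix do not match the tree leaves: "
            f"{sorted(theta.cell_types)} vs {sorted(tree.leaf_labels)}"
        )
    if list(theta.cell_types) == list(tree.leaf_labels):
        return theta
    order = [theta.cell_types.index(ct) for ct in tree.leaf_labels]
    return ProportionMatrix(
        values=theta.values[:, order],
        cell_types=list(tree.leaf_labels),
        sample_ids=theta.sample_ids,
    )


def run_cedar(
    bulk: BulkMatrix,
    theta: ProportionMatrix,
    design: DesignSpec,
    mode: Mode = "cedar-m",
    tree: CellTypeTree | None = None,
    select_threshold: float = 0.01,
    use_fdr: bool = False,
    cutoff: float = DEFAULT_POSTERIOR_CUTOFF,
) -> CedarResult:
    """Run one analysis.

    Modes: ``baseline`` stops after the full-interaction-model tests;
    ``cedar-s`` uses the single-layer hierarchy (cell types exchangeable
    under the root); ``cedar-m`` uses the supplied ``tree`` topology or,
    when none is given, estimates one by clustering the baseline
    p-value profiles. Node priors are always (re-)estimated from the
    baseline tests, also for user-supplied trees.
    """
    if tree is not None:
        theta = _align_proportions(theta, tree)
    base = baseline_test(bulk, theta, design)
    if mode == "baseline":
        return CedarResult(mode, base, None, None, None, None)
    if mode == "cedar-s":
        topology = single_layer_topology(list(theta.cell_types))
    elif mode == "cedar-m":
        if tree is not None:
            logger.info("using user-supplied tree topology; skipping estimation")
            topology = topology_of(tree)
        else:
            topology = estimate_tree(base, threshold=select_threshold, use_fdr=use_fdr)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    priors = estimate_node_priors(
        base, topology, threshold=select_threshold, use_fdr=use_fdr
    )
    fits = fit_all_states(bulk, theta, design, cell_types=priors.tree.leaf_labels)
    post = compute_posteriors(fits, priors.tree)
    post, gfdr = call_features(post, cutoff=cutoff)
    return CedarResult(mode, base, priors.tree, priors, post, gfdr)


@dataclass
class RunConfig:
    """File-level configuration of one pipeline run."""

    bulk: str
    proportions: str
    design: str
    mode: Mode = "cedar-m"
    tree: str | None = None
    tree_priors: str | None = None
    tested: str | None = None
    cell_type_specific: tuple[str, ...] = ()
    select_threshold: float = 0.01
    use_fdr: bool = False
    cutoff: float = DEFAULT_POSTERIOR_CUTOFF
    seed: int = 0
    outdir: str = "cedar_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, p in (("bulk", self.bulk), ("proportions", self.proportions), ("design", self.design)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.tree is not None and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree file not found: {self.tree}")


def run_pipeline(config: RunConfig) -> CedarResult:
    """File-based pipeline: read inputs, analyze, write all artifacts.

    Artifacts in ``config.outdir``: baseline p-values, the tree (Newick +
    YAML priors), the posterior table, per-cell-type global FDRs, and a
    provenance record sufficient to re-run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk = read_bulk(config.bulk)
    theta = read_proportions(config.proportions)
    tree = read_tree(config.tree, config.tree_priors) if config.tree else None
    if tree is not None and set(tree.leaf_labels) != set(theta.cell_types):
        raise ValueError(
            "tree leaves do not match proportion-matrix cell types; aborting "
            "before any model fitting"
        )
    design = read_design(
        config.design,
        tested=config.tested,
        cell_type_specific=config.cell_type_specific,
        sample_ids=list(bulk.sample_ids),
    )
    result = run_cedar(
        bulk,
        theta,
        design,
        mode=config.mode,
        tree=tree,
        select_threshold=config.select_threshold,
        use_fdr=config.use_fdr,
        cutoff=config.cutoff,
    )
    write_table(result.baseline.pvals, outdir / "baseline_pvalues.tsv", "feature_id")
    write_table(result.baseline.fdr, outdir / "baseline_fdr.tsv", "feature_id")
    if result.tree is not None:
        write_tree(result.tree, outdir / "tree.nwk", outdir / "tree_priors.yaml")
    if result.posteriors is not None:
        write_table(result.posteriors.to_frame(), outdir / "posteriors.tsv", "feature_id")
        gfdr = {
            ct: (None if v is None else float(v))
            for ct, v in (result.global_fdr or {}).items()
        }
        (outdir / "global_fdr.json").write_text(json.dumps(gfdr, indent=2))
    provenance = {
        "package": "cedar-csde",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "mode": config.mode,
        "seed": config.seed,
        "select_threshold": config.select_threshold,
        "use_fdr": config.use_fdr,
        "cutoff": config.cutoff,
        "inputs": {
            "bulk": str(config.bulk),
            "proportions": str(config.proportions),
            "design": str(config.design),
            "tree": str(config.tree) if config.tree else None,
        },
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    logger.info("pipeline finished; artifacts in %s", outdir)
    return result
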