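"""Empirical estimation: baseline tests, hierarchy, node priors, proportions.

The baseline per-cell-type test fits the full interaction model (the state
vector with every cell type differential — the model used by methods such
as TOAST and CellDMC) and tests each proportion-by-covariate interaction
block with a partial F-test. Those p-values then drive everything
empirical: the cell-type hierarchy is estimated by average-linkage
clustering of a correlation distance between -log10 p-value profiles, and
each tree node's prior is the fraction of features significant in any of
the node's cell types, with conditional probabilities as ratios of child
to parent priors.

A simple reference-based least-squares deconvolver is included for
estimating cell-type proportions from marker-gene profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .model import (
    BulkMatrix,
    DesignSpec,
    ProportionMatrix,
    _lstsq_fit,
    build_design,
)
from .tree import PROB_FLOOR, CellTypeTree

__all__ = [
    "BaselineTestResult",
    "TreeTopology",
    "PriorEstimate",
    "baseline_test",
    "estimate_tree",
    "estimate_node_priors",
    "estimate_proportions_rb",
    "single_layer_topology",
]

DEFAULT_SELECTION_THRESHOLD = 0.01
#: -log10 p-values are capped here before correlations (underflowed p == 0)
NEGLOG10_CAP = 300.0
MIN_SELECTED_FEATURES = 10


@dataclass
class BaselineTestResult:
    """Per-cell-type tests from the full interaction model."""

    pvals: pd.DataFrame  # G x K
    effects: pd.DataFrame  # G x K, delta-hat (first dummy column if several)
    fdr: pd.DataFrame = field(init=False)  # BH-adjusted per cell type

    def __post_init__(self) -> None:
        adj = {
            ct: multipletests(self.pvals[ct].to_numpy(), method="fdr_bh")[1]
            for ct in self.pvals.columns
        }
        self.fdr = pd.DataFrame(adj, index=self.pvals.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.pvals.columns)


def baseline_test(
    bulk: BulkMatrix, theta: ProportionMatrix, design: DesignSpec
) -> BaselineTestResult:
    """Test H0: delta_gk = 0 for each cell type under the full model.

    The full design (all interactions included) is fit once for all
    features; each cell type's interaction block is then tested with a
    nested-model F statistic

        F = ((RSS_reduced - RSS_full) / q) / (RSS_full / (N - rank_full)),

    which reduces to the squared t statistic when the block has a single
    column. P-values are scale-equivariant in Y by construction.
    """
    k = theta.n_cell_types
    n = bulk.n_samples
    y = bulk.values.T
    z_full = (1,) * k
    x_full, names = build_design(theta, design, z_full)
    if n - np.linalg.matrix_rank(x_full) <= 0:
        raise ValueError("full interaction model has no residual degrees of freedom")
    coef_full, rss_full, rank_full = _lstsq_fit(x_full, y)
    df_resid = n - rank_full
    n_dummies = design.tested.shape[0]
    pvals = np.empty((bulk.n_features, k))
    effects = np.empty((bulk.n_features, k))
    for j, ct in enumerate(theta.cell_types):
        z_red = tuple(0 if i == j else 1 for i in range(k))
        x_red, _ = build_design(theta, design, z_red)
        _, rss_red, rank_red = _lstsq_fit(x_red, y)
        q = rank_full - rank_red
        if q <= 0:
            warnings.warn(
                f"CEDAR-W004: tested block for {ct!r} is collinear; p set to 1",
                stacklevel=2,
            )
            pvals[:, j] = 1.0
            effects[:, j] = 0.0
            continue
        num = np.maximum(rss_red - rss_full, 0.0) / q
        den = rss_full / df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(den > 0, num / np.maximum(den, 1e-300), np.inf)
        pvals[:, j] = stats.f.sf(f, q, df_resid)
        first_col = names.index(
            f"theta.{ct}:{design.tested_name}" + (".0" if n_dummies > 1 else "")
        )
        effects[:, j] = coef_full[first_col]
    return BaselineTestResult(
        pvals=pd.DataFrame(pvals, index=bulk.feature_ids, columns=theta.cell_types),
        effects=pd.DataFrame(effects, index=bulk.feature_ids, columns=theta.cell_types),
    )


@dataclass
class TreeTopology:
    """A rooted topology over cell types, before priors are attached."""

    parent_map: dict[str, str | None]
    leaf_labels: list[str]


def single_layer_topology(cell_types: list[str]) -> TreeTopology:
    """All cell types independent under the root (the single-layer model)."""
    pm: dict[str, str | None] = {"root": None}
    for ct in cell_types:
        pm[ct] = "root"
    return TreeTopology(parent_map=pm, leaf_labels=list(cell_types))


def _select_features(
    test: BaselineTestResult, threshold: float, use_fdr: bool
) -> pd.DataFrame:
    table = test.fdr if use_fdr else test.pvals
    return test.pvals[(table.min(axis=1) < threshold)]


def estimate_tree(
    test: BaselineTestResult,
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
    use_fdr: bool = False,
) -> TreeTopology:
    """Hierarchical clustering of cell types from baseline p-value profiles.

    Features significant in at least one cell type (raw p or BH fdr below
    the threshold) are kept; the distance between cell types k, k' is
    (1 - cor(-log10 pval_k, -log10 pval_k')) / 2 on that set, and average
    linkage (UPGMA) supplies the bifurcating topology. With fewer than ten
    selected features the estimate is unreliable and the single-layer
    topology is returned with a warning.
    """
    cts = test.cell_types
    if len(cts) < 2:
        raise ValueError("at least two cell types are required")
    if len(cts) == 2:
        return _topology_from_merges(cts, [({cts[0]}, {cts[1]})])
    selected = _select_features(test, threshold, use_fdr)
    if len(selected) < MIN_SELECTED_FEATURES:
        warnings.warn(
            "CEDAR-W005: fewer than 10 features pass the selection threshold; "
            "falling back to the single-layer topology",
            stacklevel=2,
        )
        return single_layer_topology(cts)
    neglog = np.minimum(-np.log10(np.maximum(selected.to_numpy(), 1e-300)), NEGLOG10_CAP)
    corr = np.corrcoef(neglog.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 0.5 * (1.0 - corr)
    np.fill_diagonal(dist, 0.0)
    linkage = sch.linkage(squareform(dist, checks=False), method="average")
    return _topology_from_linkage(cts, linkage)


def _topology_from_linkage(cts: list[str], linkage: np.ndarray) -> TreeTopology:
    clusters: dict[int, set[str]] = {i: {ct} for i, ct in enumerate(cts)}
    merges: list[tuple[set[str], set[str]]] = []
    for i, (a, b, _, _) in enumerate(linkage):
        sa, sb = clusters[int(a)], clusters[int(b)]
        merges.append((sa, sb))
        clusters[len(cts) + i] = sa | sb
    return _topology_from_merges(cts, merges)


def _node_name(leafset: set[str], cts: list[str]) -> str:
    if len(leafset) == 1:
        return next(iter(leafset))
    if len(leafset) == len(cts):
        return "root"
    # deterministic internal name from the lexicographically sorted leafset
    return "|".join(sorted(leafset))


def _topology_from_merges(
    cts: list[str], merges: list[tuple[set[str], set[str]]]
) -> TreeTopology:
    pm: dict[str, str | None] = {}
    for sa, sb in merges:
        parent = _node_name(sa | sb, cts)
        pm[_node_name(sa, cts)] = parent
        pm[_node_name(sb, cts)] = parent
    pm["root"] = None
    return TreeTopology(parent_map=pm, leaf_labels=list(cts))


@dataclass
class PriorEstimate:
    """Estimated node priors attached to a topology."""

    pi: dict[str, float]  # node -> marginal prior (before clamping)
    p: dict[str, float]  # non-root node -> conditional-on-parent probability
    threshold: float
    tree: CellTypeTree


def estimate_node_priors(
    test: BaselineTestResult,
    topology: TreeTopology,
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
    use_fdr: bool = False,
) -> PriorEstimate:
    """Empirical node priors: significant-in-any-leaf fractions and ratios.

    For every node, pi-hat is the fraction of features whose minimum
    p-value over the node's leafset falls below the threshold; conditional
    probabilities are pi-hat(node) / pi-hat(parent). Leaves are handled
    identically with singleton leafsets. Estimates are clamped away from 0
    and 1 before entering the prior.
    """
    if set(topology.leaf_labels) != set(test.cell_types):
        raise ValueError("topology leaves do not match tested cell types")
    table = test.fdr if use_fdr else test.pvals
    g = len(table)
    children: dict[str, list[str]] = {}
    for node, parent in topology.parent_map.items():
        if parent is not None:
            children.setdefault(parent, []).append(node)

    leafsets: dict[str, set[str]] = {}

    def leafset(node: str) -> set[str]:
        if node not in leafsets:
            kids = children.get(node, [])
            leafsets[node] = (
                {node} if not kids else set().union(*(leafset(c) for c in kids))
            )
        return leafsets[node]

    root = next(n for n, p in topology.parent_map.items() if p is None)
    pi: dict[str, float] = {}
    for node in topology.parent_map:
        cols = sorted(leafset(node))
        pi[node] = float((table[cols].min(axis=1) < threshold).sum()) / g
    p: dict[str, float] = {}
    for node, parent in topology.parent_map.items():
        if parent is None:
            continue
        if pi[parent] == 0.0:
            warnings.warn(
                f"CEDAR-W006: parent prior of {node!r} is zero; conditional set to 0",
                stacklevel=2,
            )
            p[node] = 0.0
        else:
            p[node] = min(pi[node] / pi[parent], 1.0)
    tree = CellTypeTree(
        topology.parent_map,
        topology.leaf_labels,
        root_pi=max(pi[root], PROB_FLOOR),
        cond_p=p,
    )
    return PriorEstimate(pi=pi, p=p, threshold=threshold, tree=tree)


def estimate_proportions_rb(
    bulk: BulkMatrix, reference: pd.DataFrame
) -> ProportionMatrix:
    """Reference-based proportion estimation by per-sample least squares.

    ``reference`` holds mean pure-cell profiles over marker features
    (features x cell types). Each sample's bulk marker vector is regressed
    on the reference columns; negative coefficients are truncated at zero
    and the result renormalized to sum to one.
    """
    markers = [f for f in reference.index if f in set(bulk.feature_ids)]
    if not markers:
        raise ValueError("no marker features shared between bulk and reference")
    ref = reference.loc[markers].to_numpy(dtype=float)
    pos = {f: i for i, f in enumerate(bulk.feature_ids)}
    yb = bulk.values[[pos[f] for f in markers], :]  # M x N
    if np.linalg.matrix_rank(ref) < ref.shape[1]:
        warnings.warn(
            "CEDAR-W007: collinear reference profiles; minimum-norm solution used",
            stacklevel=2,
        )
    coef, _, _, _ = np.linalg.lstsq(ref, yb, rcond=None)  # K x N
    coef = np.maximum(coef, 0.0)
    sums = coef.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("a sample's estimated proportions are all zero")
    props = (coef / sums).T
    return ProportionMatrix(
        values=props,
        cell_types=list(reference.columns),
        sample_ids=list(bulk.sample_ids),
    )
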