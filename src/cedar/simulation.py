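"""Bulk-mixture simulation with tree-correlated differential states.

The generator emulates a two-group (case/control) bulk expression study of
whole-blood mixtures. Per-feature differential states are drawn top-down
from a cell-type hierarchy, so nearby cell types share differential genes
at the rates the tree's node probabilities imply. Pure cell-type profiles
are log-normal around per-(gene, cell type) baselines; differential
entries shift the case-group log2 mean by a fold change with |lfc| ~
N(1, 0.2^2) and a random sign. Sample compositions come from one Dirichlet
distribution, identical for cases and controls (no composition shift
between groups), and the observed bulk value is the proportion-weighted
mixture plus Gaussian noise whose scale grows with the gene's expression
(eta_g = 0.1 x the larger of the two group means of the mixed signal).

Baselines default to a synthetic stand-in for purified immune-cell
microarray profiles: mu_gk ~ N(6, 1.5^2) on the log2 scale and
sigma_gk = 0.1 + |N(0, 0.2^2)|; a user table of (mu_gk, sigma_gk) can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .model import BulkMatrix, DesignSpec, ProportionMatrix
from .tree import CellTypeTree

__all__ = [
    "BLOOD6_LABELS",
    "BLOOD6_ALPHA",
    "blood6_tree",
    "four_celltype_tree",
    "SimulationConfig",
    "SimulationTruth",
    "draw_states",
    "simulate_dataset",
]

#: six immune cell types in the hierarchy's numbering
BLOOD6_LABELS = ("neutrophils", "monocytes", "CD4", "CD8", "B", "NK")

#: Dirichlet concentration of whole-blood compositions, aligned with
#: BLOOD6_LABELS (neutrophils dominate at a mean proportion of ~0.63)
BLOOD6_ALPHA = {
    "neutrophils": 27.94,
    "monocytes": 4.64,
    "CD8": 2.47,
    "CD4": 4.87,
    "B": 2.30,
    "NK": 2.21,
}

FOUR_CT_LABELS = ("neutrophils", "monocytes", "CD4", "CD8")
FOUR_CT_ALPHA = {"neutrophils": 27.94, "monocytes": 4.64, "CD8": 2.47, "CD4": 9.38}


def blood6_tree() -> CellTypeTree:
    """Default six-cell-type hierarchy.

    Every leaf's marginal differential prior is 0.10; neutrophils and
    monocytes overlap in 80% of their differential genes, CD4/CD8 in 80%,
    CD4-B in 62.5%, and CD4-NK in 50%.
    """
    pm: dict[str, str | None] = {
        "root": None,
        "myeloid": "root",
        "lymphoid": "root",
        "neutrophils": "myeloid",
        "monocytes": "myeloid",
        "T_B": "lymphoid",
        "NK": "lymphoid",
        "T": "T_B",
        "B": "T_B",
        "CD4": "T",
        "CD8": "T",
    }
    cond_p = {
        "myeloid": 0.3125,
        "neutrophils": 0.8,
        "monocytes": 0.8,
        "lymphoid": 0.5,
        "T_B": 0.8,
        "NK": 0.5,
        "T": 0.78125,
        "B": 0.625,
        "CD4": 0.8,
        "CD8": 0.8,
    }
    return CellTypeTree(pm, list(BLOOD6_LABELS), root_pi=0.4, cond_p=cond_p)


def four_celltype_tree(
    pattern: Literal["a", "b", "c", "d", "e", "f"],
    overlap: float = 0.9,
    leaf_pi: float = 0.1,
    cross_overlap: float = 0.25,
) -> CellTypeTree:
    """Four-cell-type hierarchies spanning the correlation patterns.

    ``overlap`` is the expected fraction of one cell type's differential
    genes shared with its correlated partner (0.9 "strong", 0.5 "weak");
    every leaf keeps marginal prior ``leaf_pi``. Patterns: (a) all
    independent; (b) all exchangeable under a sub-certain root
    (single-layer); (c) only CD4/CD8 correlated; (d) only
    neutrophils/monocytes correlated; (e) both pairs correlated, pairs
    mutually independent; (f) both pairs correlated and the pairs further
    coupled through the root at ``cross_overlap``.
    """
    cts = list(FOUR_CT_LABELS)
    pair1 = ("neutrophils", "monocytes")
    pair2 = ("CD4", "CD8")

    def pair_params(rho: float) -> tuple[float, float]:
        # parent pi and leaf cond so each leaf keeps leaf_pi and the pair
        # overlaps at rho
        return leaf_pi / rho, rho

    pm: dict[str, str | None] = {"root": None}
    cond: dict[str, float] = {}
    if pattern == "a":
        root_pi = 1.0
        for ct in cts:
            pm[ct] = "root"
            cond[ct] = leaf_pi
    elif pattern == "b":
        root_pi = leaf_pi / overlap
        for ct in cts:
            pm[ct] = "root"
            cond[ct] = overlap
    elif pattern in ("c", "d"):
        root_pi = 1.0
        corr = pair2 if pattern == "c" else pair1
        node_pi, leaf_p = pair_params(overlap)
        pm["pair"] = "root"
        cond["pair"] = node_pi
        for ct in cts:
            if ct in corr:
                pm[ct] = "pair"
                cond[ct] = leaf_p
            else:
                pm[ct] = "root"
                cond[ct] = leaf_pi
    elif pattern == "e":
        root_pi = 1.0
        node_pi, leaf_p = pair_params(overlap)
        for name, pair in (("myeloid", pair1), ("T", pair2)):
            pm[name] = "root"
            cond[name] = node_pi
            for ct in pair:
                pm[ct] = name
                cond[ct] = leaf_p
    elif pattern == "f":
        # cross-pair overlap = (pair cond x leaf cond) => root pi follows
        root_pi = leaf_pi / cross_overlap
        pair_cond = cross_overlap / overlap
        for name, pair in (("myeloid", pair1), ("T", pair2)):
            pm[name] = "root"
            cond[name] = pair_cond
            for ct in pair:
                pm[ct] = name
                cond[ct] = overlap
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {pattern!r}")
    return CellTypeTree(pm, cts, root_pi=root_pi, cond_p=cond)


@dataclass
class SimulationConfig:
    """Conditions of one simulated two-group bulk study."""

    n_features: int = 12402
    n_per_group: int = 100
    tree: CellTypeTree = field(default_factory=blood6_tree)
    dirichlet_alpha: dict[str, float] = field(
        default_factory=lambda: dict(BLOOD6_ALPHA)
    )
    lfc_mean: float = 1.0
    lfc_sd: float = 0.2
    noise_multiplier: float = 0.1
    #: synthetic baseline hyper-parameters (log2 scale)
    baseline_mu_mean: float = 6.0
    baseline_mu_sd: float = 1.5
    baseline_sigma_base: float = 0.1
    baseline_sigma_sd: float = 0.2
    #: optional user baselines: (features x cell types) tables of mu and sigma
    baseline_mu: pd.DataFrame | None = None
    baseline_sigma: pd.DataFrame | None = None
    #: "per_gene" shares one up/down direction across a gene's differential
    #: cell types; "per_gene_cell_type" redraws it independently
    direction_mode: Literal["per_gene", "per_gene_cell_type"] = "per_gene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_per_group < 2:
            raise ValueError("need at least 1 feature and 2 samples per group")
        missing = [ct for ct in self.tree.leaf_labels if ct not in self.dirichlet_alpha]
        if missing:
            raise ValueError(f"no Dirichlet parameter for cell types {missing}")
        if any(a <= 0 for a in self.dirichlet_alpha.values()):
            raise ValueError("Dirichlet parameters must be positive")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.tree.leaf_labels)


@dataclass
class SimulationTruth:
    """Generative record of one simulated dataset."""

    z: pd.DataFrame  # G x K binary differential states
    direction: pd.DataFrame  # G x K in {-1, 0, +1}
    lfc: pd.DataFrame  # G x K log2 fold changes (0 where not differential)
    group: np.ndarray  # N, 0 = control, 1 = case
    pure_profiles: np.ndarray | None  # G x N x K expression-scale X_gik
    baseline_mu: pd.DataFrame
    baseline_sigma: pd.DataFrame

    def design(self) -> DesignSpec:
        return DesignSpec(tested=self.group.astype(float), tested_name="group")


def draw_states(
    tree: CellTypeTree, n_features: int, rng: np.random.Generator | int
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Sample per-feature node states top-down through the hierarchy.

    The root is Bernoulli(pi); every other node is Bernoulli(p) where its
    parent's state is 1 and 0 elsewhere. Returns the G x K leaf-state
    matrix (columns in leaf order) and the full per-node state record.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    states: dict[str, np.ndarray] = {}

    def visit(name: str, parent_state: np.ndarray | None) -> None:
        node = tree.nodes[name]
        if parent_state is None:
            s = (rng.random(n_features) < tree.root_pi).astype(np.int8)
        else:
            s = np.where(
                parent_state == 1,
                (rng.random(n_features) < node.cond_p).astype(np.int8),
                0,
            ).astype(np.int8)
        states[name] = s
        for c in node.children:
            visit(c, s)

    visit(tree.root, None)
    z = np.column_stack([states[l] for l in tree.leaf_labels])
    return z, states


def _baselines(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame]:
    g = config.n_features
    cts = list(config.cell_types)
    k = len(cts)
    features = [f"gene{i + 1}" for i in range(g)]
    if config.baseline_mu is not None or config.baseline_sigma is not None:
        if config.baseline_mu is None or config.baseline_sigma is None:
            raise ValueError("baseline mu and sigma tables must both be supplied")
        mu_t, sd_t = config.baseline_mu, config.baseline_sigma
        if list(mu_t.columns) != cts or list(sd_t.columns) != cts:
            raise ValueError("baseline table columns do not match tree cell types")
        if len(mu_t) != g or len(sd_t) != g:
            raise ValueError(
                f"baseline tables have {len(mu_t)} rows, expected {g} features"
            )
        mu, sd = mu_t.to_numpy(dtype=float), sd_t.to_numpy(dtype=float)
        features = list(mu_t.index.astype(str))
    else:
        mu = rng.normal(config.baseline_mu_mean, config.baseline_mu_sd, size=(g, k))
        sd = config.baseline_sigma_base + np.abs(
            rng.normal(0.0, config.baseline_sigma_sd, size=(g, k))
        )
    mu_frame = pd.DataFrame(mu, index=features, columns=cts)
    sd_frame = pd.DataFrame(sd, index=features, columns=cts)
    return mu, sd, mu_frame, sd_frame


def simulate_dataset(
    config: SimulationConfig, keep_pure_profiles: bool = False
) -> tuple[BulkMatrix, ProportionMatrix, SimulationTruth]:
    """Generate one bulk dataset with its composition matrix and truth.

    Deterministic given ``config.seed``: identical configurations yield
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    g, s = config.n_features, config.n_per_group
    cts = list(config.cell_types)
    k = len(cts)
    n = 2 * s
    group = np.repeat([0, 1], s)

    z, _ = draw_states(config.tree, g, rng)
    mu, sd, mu_frame, sd_frame = _baselines(config, rng)
    features = list(mu_frame.index)

    if config.direction_mode == "per_gene":
        gene_dir = np.where(rng.random(g) < 0.5, 1.0, -1.0)
        direction = z * gene_dir[:, None]
    else:
        direction = z * np.where(rng.random((g, k)) < 0.5, 1.0, -1.0)
    lfc = direction * np.abs(rng.normal(config.lfc_mean, config.lfc_sd, size=(g, k)))
    lfc = np.where(z == 1, lfc, 0.0)

    alpha = np.array([config.dirichlet_alpha[ct] for ct in cts])
    theta = rng.dirichlet(alpha, size=n)  # N x K

    # pure profiles on the expression scale; the case group's log2 mean is
    # shifted by lfc for differential entries only
    log_x = rng.normal(0.0, 1.0, size=(g, n, k)) * sd[:, None, :] + mu[:, None, :]
    log_x += (group[None, :, None] == 1) * lfc[:, None, :]
    x = np.exp2(log_x)

    mixed = np.einsum("gnk,nk->gn", x, theta)
    ctrl_mean = mixed[:, group == 0].mean(axis=1)
    case_mean = mixed[:, group == 1].mean(axis=1)
    eta = config.noise_multiplier * np.maximum(ctrl_mean, case_mean)
    y = mixed + rng.normal(0.0, 1.0, size=(g, n)) * eta[:, None]

    sample_ids = [f"control_{i + 1}" for i in range(s)] + [
        f"case_{i + 1}" for i in range(s)
    ]
    bulk = BulkMatrix(values=y, feature_ids=features, sample_ids=sample_ids)
    props = ProportionMatrix(values=theta, cell_types=cts, sample_ids=sample_ids)
    truth = SimulationTruth(
        z=pd.DataFrame(z, index=features, columns=cts),
        direction=pd.DataFrame(direction, index=features, columns=cts),
        lfc=pd.DataFrame(lfc, index=features, columns=cts),
        group=group,
        pure_profiles=x if keep_pure_profiles else None,
        baseline_mu=mu_frame,
        baseline_sigma=sd_frame,
    )
    return bulk, props, truth
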