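import numpy as np
import pytest

from cedar import (
    CellTypeTree,
    DesignSpec,
    SimulationConfig,
    simulate_dataset,
)
from cedar.simulation import blood6_tree


@pytest.fixture
def fig_tree() -> CellTypeTree:
    """Three cell types: one under the root, two sharing an internal node.

    Marginal leaf priors are (0.30, 0.06, 0.04); the ct2/ct3 pair shares
    an internal node with marginal 0.08.
    """
    parent_map = {"root": None, "ct1": "root", "n23": "root", "ct2": "n23", "ct3": "n23"}
    cond_p = {"ct1": 0.75, "n23": 0.2, "ct2": 0.75, "ct3": 0.5}
    return CellTypeTree(parent_map, ["ct1", "ct2", "ct3"], root_pi=0.4, cond_p=cond_p)


@pytest.fixture
def blood_tree() -> CellTypeTree:
    return blood6_tree()


def random_tree(rng: np.random.Generator, n_leaves: int) -> CellTypeTree:
    """Random topology and probabilities over n_leaves cell types."""
    labels = [f"ct{i + 1}" for i in range(n_leaves)]
    parent_map: dict[str, str | None] = {"root": None}
    cond_p: dict[str, float] = {}
    counter = [0]

    def grow(parent: str, members: list[str]) -> None:
        if len(members) == 1:
            parent_map[members[0]] = parent
            cond_p[members[0]] = rng.uniform(0.05, 1.0)
            return
        n_parts = rng.integers(2, len(members) + 1)
        assignment = rng.integers(0, n_parts, size=len(members))
        parts = [
            [m for m, a in zip(members, assignment) if a == i] for i in range(n_parts)
        ]
        parts = [p for p in parts if p]
        if len(parts) == 1:  # degenerate split; force a real one
            parts = [members[:1], members[1:]]
        for part in parts:
            if len(part) == 1:
                grow(parent, part)
            else:
                counter[0] += 1
                name = f"n{counter[0]}"
                parent_map[name] = parent
                cond_p[name] = rng.uniform(0.05, 1.0)
                grow(name, part)

    grow("root", labels)
    return CellTypeTree(parent_map, labels, root_pi=rng.uniform(0.05, 1.0), cond_p=cond_p)


def pair_tree(rho: float = 0.8, leaf_pi: float = 0.1) -> CellTypeTree:
    """Two correlated cell types: each leaf at leaf_pi, overlap rho."""
    pm = {"root": None, "ct1": "root", "ct2": "root"}
    return CellTypeTree(
        pm, ["ct1", "ct2"], root_pi=leaf_pi / rho, cond_p={"ct1": rho, "ct2": rho}
    )


@pytest.fixture
def toy_dataset():
    """Small three-cell-type simulated study (G=20, N=2x15), fixed seed."""
    pm = {"root": None, "n12": "root", "ct1": "n12", "ct2": "n12", "ct3": "root"}
    tree = CellTypeTree(
        pm,
        ["ct1", "ct2", "ct3"],
        root_pi=0.5,
        cond_p={"n12": 0.6, "ct1": 0.8, "ct2": 0.8, "ct3": 0.4},
    )
    config = SimulationConfig(
        n_features=20,
        n_per_group=15,
        tree=tree,
        dirichlet_alpha={"ct1": 10.0, "ct2": 5.0, "ct3": 5.0},
        seed=42,
    )
    bulk, props, truth = simulate_dataset(config)
    return bulk, props, truth, tree


def group_design(n_per_group: int) -> DesignSpec:
    return DesignSpec(
        tested=np.repeat([0.0, 1.0], n_per_group), tested_name="group"
    )
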