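"""Cell-type hierarchy and exact priors over latent differential states.

The hierarchy is a rooted tree (not necessarily bifurcating) whose leaves
are the K cell types. Every node carries a binary latent state: ``Z_k`` for
leaf cell types ("is feature g differential in cell type k?") and ``D`` for
internal nodes, which act as shared switches. The state of any non-root
node can be 1 only if its parent's state is 1; conditional on a parent in
state 1, a node is 1 with its conditional probability ``p``, and sibling
subtrees are independent. The root is 1 with probability ``pi``. This
factorized prior induces positive correlation between the differential
states of nearby cell types while leaving distant ones nearly independent.

All prior computations here are exact: either by recursive marginalization
over the internal-node states (any K) or by explicit enumeration of valid
state configurations (small K, used mainly as an oracle).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import yaml

__all__ = [
    "PROB_FLOOR",
    "CellTypeTree",
    "StateConfig",
    "build_single_layer_tree",
    "marginal_leaf_prior",
    "enumerate_state_configs",
    "joint_prior_event",
]

#: probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] so that the
#: posterior (a prior-weighted ratio) never degenerates to 0/0
PROB_FLOOR = 1e-10

#: hard cap on K for paths that enumerate all 2^K leaf-state vectors
ENUMERATION_CAP = 12


def _clamp(p: float) -> float:
    return min(max(float(p), PROB_FLOOR), 1.0 - PROB_FLOOR)


class TreeError(ValueError):
    """Raised for structurally invalid trees or inconsistent probabilities."""


class CapacityError(ValueError):
    """Raised when an enumeration path is requested above the K cap."""


@dataclass
class _Node:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    leafset: frozenset[str] = frozenset()
    cond_p: float = 1.0  # P(state=1 | parent state=1); unused for root


class CellTypeTree:
    """Rooted cell-type hierarchy with per-node prior probabilities.

    Parameters
    ----------
    parent_map
        Mapping node name -> parent name; exactly one node (the root) maps
        to ``None``. Leaf nodes must be named by the cell-type labels.
    leaf_labels
        Cell-type names in their fixed column order k = 1..K.
    root_pi
        Marginal probability that the root state is 1.
    cond_p
        Mapping node name -> conditional probability of state 1 given the
        parent is in state 1, for every non-root node.
    """

    def __init__(
        self,
        parent_map: Mapping[str, str | None],
        leaf_labels: Sequence[str],
        root_pi: float,
        cond_p: Mapping[str, float],
    ) -> None:
        roots = [n for n, p in parent_map.items() if p is None]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.leaf_labels = tuple(leaf_labels)
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            raise TreeError("duplicated cell-type labels")
        self.nodes: dict[str, _Node] = {
            name: _Node(name=name, parent=parent) for name, parent in parent_map.items()
        }
        for name, node in self.nodes.items():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise TreeError(f"unknown parent {node.parent!r} of node {name!r}")
                self.nodes[node.parent].children.append(name)
        # children in canonical order (sorted leafset) so that results do not
        # depend on the serialization order of the input
        leaves = {n for n, nd in self.nodes.items() if not nd.children}
        if leaves != set(self.leaf_labels):
            raise TreeError(
                f"tree leaves {sorted(leaves)} do not match cell types "
                f"{sorted(self.leaf_labels)}"
            )
        self._compute_leafsets(self.root)
        for node in self.nodes.values():
            node.children.sort(key=lambda c: tuple(sorted(self.nodes[c].leafset)))
        self.root_pi = _clamp(root_pi)
        for name in self.nodes:
            if name == self.root:
                continue
            if name not in cond_p:
                raise TreeError(f"missing conditional probability for node {name!r}")
            p = float(cond_p[name])
            if not 0.0 <= p <= 1.0:
                raise TreeError(f"probability {p} for node {name!r} outside [0, 1]")
            self.nodes[name].cond_p = _clamp(p)
        self._check_acyclic()

    # -- construction helpers -------------------------------------------------

    def _compute_leafsets(self, name: str) -> frozenset[str]:
        node = self.nodes[name]
        if not node.children:
            node.leafset = frozenset([name])
        else:
            sets = [self._compute_leafsets(c) for c in node.children]
            union: set[str] = set()
            for s in sets:
                if union & s:
                    raise TreeError("children leafsets overlap")
                union |= s
            node.leafset = frozenset(union)
        return node.leafset

    def _check_acyclic(self) -> None:
        for name in self.nodes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise TreeError("cycle detected in parent pointers")
                seen.add(cur)
                cur = self.nodes[cur].parent

    # -- basic accessors ------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def internal_nodes(self) -> list[str]:
        """Non-leaf node names, root first, in canonical (pre-order) order."""
        order: list[str] = []

        def visit(name: str) -> None:
            node = self.nodes[name]
            if node.children:
                order.append(name)
                for c in node.children:
                    visit(c)

        visit(self.root)
        return order

    def path_to_root(self, name: str) -> list[str]:
        out = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def node_marginal(self, name: str) -> float:
        """Marginal P(state of node = 1): root pi times cond_p down the path."""
        prob = self.root_pi
        for n in self.path_to_root(name):
            if n != self.root:
                prob *= self.nodes[n].cond_p
        return prob

    # -- exact prior computations --------------------------------------------

    def joint_prior_event(self, constraints: Mapping[str, int]) -> float:
        """Exact prior probability of a partial leaf-state event.

        ``constraints`` maps cell-type labels to required states (0 or 1);
        unconstrained leaves and all internal-node states are marginalized
        by an upward tree recursion, so the cost is linear in the number of
        nodes regardless of K.
        """
        for label, state in constraints.items():
            if label not in self.leaf_labels:
                raise TreeError(f"unknown cell-type label {label!r}")
            if state not in (0, 1):
                raise TreeError(f"state for {label!r} must be 0 or 1, got {state!r}")

        def subtree(name: str, parent_state: int) -> float:
            node = self.nodes[name]
            if not node.children:  # leaf
                want = constraints.get(name)
                if want is None:
                    return 1.0
                p1 = node.cond_p * parent_state
                return p1 if want == 1 else 1.0 - p1
            p1 = node.cond_p * parent_state if name != self.root else self.root_pi
            total = 0.0
            for state, w in ((1, p1), (0, 1.0 - p1)):
                if w == 0.0:
                    continue
                prod = w
                for c in node.children:
                    prod *= subtree(c, state)
                    if prod == 0.0:
                        break
                total += prod
            return total

        return subtree(self.root, 1)

    def z_prior(self, z: Sequence[int]) -> float:
        """Prior mass of a full leaf-state vector, internal states summed out."""
        if len(z) != self.n_leaves:
            raise TreeError(f"z has length {len(z)}, expected {self.n_leaves}")
        return self.joint_prior_event(dict(zip(self.leaf_labels, z)))

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with per-node `[&pi=..,p=..]` probability comments."""

        def render(name: str) -> str:
            node = self.nodes[name]
            if name == self.root:
                ann = f"[&pi={self.root_pi:.12g}]"
            else:
                ann = f"[&pi={self.node_marginal(name):.12g},p={node.cond_p:.12g}]"
            if not node.children:
                return f"{name}{ann}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){name}{ann}"

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, priors: Mapping[str, Mapping[str, float]] | None = None) -> "CellTypeTree":
        """Parse a Newick tree, reading probabilities from `[&pi=..,p=..]`
        comments or, if given, from a sidecar mapping node name -> {pi, p}.
        """
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
        parent_map: dict[str, str | None] = {}
        ann: dict[str, dict[str, float]] = {}
        counter = itertools.count(1)
        names: dict[int, str] = {}

        for nd in dtree.preorder_node_iter():
            if nd.taxon is not None:
                name = nd.taxon.label
            elif nd.label:
                name = nd.label
            else:
                name = f"node{next(counter)}"
            names[id(nd)] = name
            parent_map[name] = names[id(nd.parent_node)] if nd.parent_node else None
            meta = {a.name: float(a.value) for a in nd.annotations}
            if priors is not None and name in priors:
                meta.update({k: float(v) for k, v in priors[name].items()})
            ann[name] = meta

        root = next(n for n, p in parent_map.items() if p is None)
        leaf_labels = [
            nd.taxon.label for nd in dtree.leaf_node_iter() if nd.taxon is not None
        ]
        if "pi" not in ann.get(root, {}):
            raise TreeError("root node has no 'pi' annotation (and no sidecar entry)")
        root_pi = ann[root]["pi"]
        cond_p: dict[str, float] = {}
        for name, meta in ann.items():
            if name == root:
                continue
            if "p" in meta:
                cond_p[name] = meta["p"]
            elif "pi" in meta:
                # derive conditional from marginals if only pi was stored
                parent = parent_map[name]
                parent_pi = ann.get(parent, {}).get("pi")
                if parent_pi is None:
                    raise TreeError(f"cannot derive p for node {name!r}")
                cond_p[name] = meta["pi"] / parent_pi
            else:
                raise TreeError(f"node {name!r} has neither 'p' nor 'pi'")
        return cls(parent_map, leaf_labels, root_pi, cond_p)

    def priors_to_yaml(self) -> str:
        """YAML sidecar mapping node name -> {pi, p}."""
        out: dict[str, dict[str, float]] = {}
        for name in self.nodes:
            entry: dict[str, float] = {"pi": float(self.node_marginal(name))}
            if name != self.root:
                entry["p"] = float(self.nodes[name].cond_p)
            out[name] = entry
        return yaml.safe_dump({"root": self.root, "nodes": out}, sort_keys=True)

    @classmethod
    def from_newick_with_yaml(cls, newick: str, yaml_text: str) -> "CellTypeTree":
        doc = yaml.safe_load(yaml_text)
        return cls.from_newick(newick, priors=doc["nodes"])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CellTypeTree(K={self.n_leaves}, leaves={list(self.leaf_labels)}, "
            f"root_pi={self.root_pi:.4g})"
        )


@dataclass(frozen=True)
class StateConfig:
    """One joint assignment of leaf states z and internal-node states d."""

    z: tuple[int, ...]
    d: tuple[int, ...]  # aligned with tree.internal_nodes()
    prior_mass: float


def marginal_leaf_prior(tree: CellTypeTree, cell_type: str | int) -> float:
    """Marginal prior P(Z_k = 1): root pi times cond_p along the root path."""
    if isinstance(cell_type, int):
        try:
            label = tree.leaf_labels[cell_type]
        except IndexError:
            raise TreeError(f"cell-type index {cell_type} out of range") from None
    else:
        label = cell_type
        if label not in tree.leaf_labels:
            raise TreeError(f"unknown cell-type label {label!r}")
    return tree.node_marginal(label)


def enumerate_state_configs(tree: CellTypeTree) -> list[StateConfig]:
    """All valid (z, d) configurations with their exact prior masses.

    A configuration is valid iff every node in state 1 has its parent in
    state 1. Masses follow the factorized prior and sum to one. Intended
    for small K (oracle / exact small-problem path); the recursive
    marginalization in :meth:`CellTypeTree.joint_prior_event` covers any K.
    """
    if tree.n_leaves > ENUMERATION_CAP:
        raise CapacityError(
            f"K={tree.n_leaves} exceeds the enumeration cap {ENUMERATION_CAP}; "
            "use joint_prior_event / z_prior (exact marginalization) instead"
        )
    internal = tree.internal_nodes()
    configs: list[StateConfig] = []
    states: dict[str, int] = {}

    def assign(pending: list[str], mass: float) -> None:
        if not pending:
            z = tuple(states[l] for l in tree.leaf_labels)
            d = tuple(states[n] for n in internal)
            configs.append(StateConfig(z=z, d=d, prior_mass=mass))
            return
        name, *rest = pending
        node = tree.nodes[name]
        if name == tree.root:
            p1 = tree.root_pi
        else:
            p1 = node.cond_p if states[node.parent] == 1 else 0.0
        for state, w in ((0, 1.0 - p1), (1, p1)):
            if w == 0.0:
                continue
            states[name] = state
            assign(rest, mass * w)
        del states[name]

    # topological order: parents before children
    order: list[str] = []

    def topo(name: str) -> None:
        order.append(name)
        for c in tree.nodes[name].children:
            topo(c)

    topo(tree.root)
    assign(order, 1.0)
    return configs


def joint_prior_event(tree: CellTypeTree, constraints: Mapping[str, int]) -> float:
    """Prior probability that the constrained leaves take the given states."""
    return tree.joint_prior_event(constraints)


def build_single_layer_tree(
    leaf_pis: Mapping[str, float] | Sequence[float],
    root_pi: float,
    leaf_labels: Iterable[str] | None = None,
) -> CellTypeTree:
    """Single-layer hierarchy: all cell types independent under one root.

    The conditional probability of each leaf is its marginal prior divided
    by the root prior, so each leaf keeps its marginal while the root state
    is the only source of correlation.
    """
    if isinstance(leaf_pis, Mapping):
        labels = list(leaf_pis.keys())
        pis = [float(leaf_pis[l]) for l in labels]
    else:
        pis = [float(p) for p in leaf_pis]
        labels = list(leaf_labels) if leaf_labels is not None else [
            f"ct{i + 1}" for i in range(len(pis))
        ]
    if root_pi <= 0:
        raise TreeError("root probability must be positive")
    for label, p in zip(labels, pis):
        if p > root_pi:
            raise TreeError(
                f"leaf prior {p} for {label!r} exceeds root prior {root_pi}: "
                "a child's marginal cannot exceed its parent's"
            )
    parent_map: dict[str, str | None] = {"root": None}
    cond_p: dict[str, float] = {}
    for label, p in zip(labels, pis):
        parent_map[label] = "root"
        cond_p[label] = p / root_pi
    return CellTypeTree(parent_map, labels, root_pi, cond_p)
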