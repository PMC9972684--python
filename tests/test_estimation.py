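"""Baseline tests, hierarchy estimation, prior estimation, deconvolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cedar import (
    BulkMatrix,
    ProportionMatrix,
    SimulationConfig,
    baseline_test,
    build_single_layer_tree,
    estimate_node_priors,
    estimate_proportions_rb,
    estimate_tree,
    simulate_dataset,
)
from cedar.estimation import BaselineTestResult, single_layer_topology
from cedar.simulation import four_celltype_tree
from cedar.tree import PROB_FLOOR

from conftest import group_design


def null_dataset(g=2000, n_per_group=50, k=3, seed=0):
    """No differential signal anywhere (root prior forced to zero)."""
    tree = build_single_layer_tree([0.0] * k, root_pi=1.0)
    alpha = {ct: 5.0 for ct in tree.leaf_labels}
    config = SimulationConfig(
        n_features=g, n_per_group=n_per_group, tree=tree,
        dirichlet_alpha=alpha, seed=seed,
    )
    return simulate_dataset(config)


def make_result(pvals: np.ndarray, cts: list[str]) -> BaselineTestResult:
    g = len(pvals)
    return BaselineTestResult(
        pvals=pd.DataFrame(pvals, index=[f"g{i}" for i in range(g)], columns=cts),
        effects=pd.DataFrame(
            np.zeros_like(pvals), index=[f"g{i}" for i in range(g)], columns=cts
        ),
    )


class TestBaselineTest:
    def test_null_pvalues_are_uniform(self):
        bulk, props, truth = null_dataset(seed=11)
        result = baseline_test(bulk, props, truth.design())
        for ct in props.cell_types:
            ks = stats.kstest(result.pvals[ct].to_numpy(), "uniform")
            assert ks.pvalue > 0.01, f"{ct}: KS p={ks.pvalue:.4f}"

    def test_f_statistic_matches_nested_rss_oracle(self):
        # one feature, K=2, N=10, fixed printed values
        theta_vals = np.array(
            [
                [0.8, 0.2], [0.7, 0.3], [0.6, 0.4], [0.75, 0.25], [0.65, 0.35],
                [0.55, 0.45], [0.85, 0.15], [0.5, 0.5], [0.72, 0.28], [0.68, 0.32],
            ]
        )
        y = np.array([[3.2, 2.8, 2.5, 3.0, 2.7, 2.9, 3.4, 2.2, 3.6, 3.1]])
        a = np.array([0.0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        theta = ProportionMatrix(values=theta_vals, cell_types=["ct1", "ct2"])
        bulk = BulkMatrix(values=y, feature_ids=["g1"], sample_ids=[f"s{i}" for i in range(10)])
        design_spec = group_design(5)
        result = baseline_test(bulk, theta, design_spec)

        # independent oracle: explicit normal equations on hand-built designs
        def rss_of(cols):
            x = np.column_stack(cols)
            beta = np.linalg.solve(x.T @ x, x.T @ y[0])
            return float(np.sum((y[0] - x @ beta) ** 2)), x.shape[1]

        t1, t2 = theta_vals[:, 0], theta_vals[:, 1]
        rss_full, p_full = rss_of([t1, t2, t1 * a, t2 * a])
        for j, drop in enumerate([t1 * a, t2 * a]):
            keep = [t1, t2, t2 * a] if j == 0 else [t1, t2, t1 * a]
            rss_red, _ = rss_of(keep)
            f = (rss_red - rss_full) / (rss_full / (10 - p_full))
            p_oracle = stats.f.sf(f, 1, 10 - p_full)
            assert result.pvals.iloc[0, j] == pytest.approx(p_oracle, abs=1e-10)

    def test_pvalues_scale_equivariant(self, toy_dataset):
        bulk, props, truth, _ = toy_dataset
        r1 = baseline_test(bulk, props, truth.design())
        scaled = BulkMatrix(
            values=bulk.values * 10.0,
            feature_ids=bulk.feature_ids,
            sample_ids=bulk.sample_ids,
        )
        r2 = baseline_test(scaled, props, truth.design())
        np.testing.assert_allclose(
            r1.pvals.to_numpy(), r2.pvals.to_numpy(), atol=1e-10
        )

    def test_bh_adjustment_is_monotone_and_bounded(self, toy_dataset):
        bulk, props, truth, _ = toy_dataset
        r = baseline_test(bulk, props, truth.design())
        assert ((r.fdr.to_numpy() >= r.pvals.to_numpy() - 1e-12).all())
        assert (r.fdr.to_numpy() <= 1.0).all()


class TestEstimateTree:
    def test_two_cell_types_have_unique_topology(self):
        rng = np.random.default_rng(0)
        result = make_result(rng.uniform(size=(100, 2)), ["a", "b"])
        topo = estimate_tree(result)
        assert topo.parent_map == {"a": "root", "b": "root", "root": None}

    def test_identical_pvalues_merge_first(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=(200, 3)) * 0.05  # all selected
        p[:, 1] = p[:, 0]  # cell types a and b perfectly correlated
        topo = estimate_tree(make_result(p, ["a", "b", "c"]), threshold=0.2)
        assert topo.parent_map["a"] == topo.parent_map["b"] != "root"

    def test_too_few_selected_features_falls_back_to_single_layer(self):
        p = np.full((100, 3), 0.999)
        with pytest.warns(UserWarning, match="CEDAR-W005"):
            topo = estimate_tree(make_result(p, ["a", "b", "c"]))
        assert topo.parent_map == single_layer_topology(["a", "b", "c"]).parent_map

    def test_block_correlated_pvalues_recover_pairs(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            g = 500
            shared12 = rng.normal(size=g) * 3
            shared34 = rng.normal(size=g) * 3
            z = np.column_stack(
                [
                    shared12 + rng.normal(size=g),
                    shared12 + rng.normal(size=g),
                    shared34 + rng.normal(size=g),
                    shared34 + rng.normal(size=g),
                ]
            )
            p = 2 * stats.norm.sf(np.abs(z))
            topo = estimate_tree(make_result(p, ["a", "b", "c", "d"]), threshold=0.05)
            clades = _nontrivial_clades(topo)
            if frozenset(["a", "b"]) in clades and frozenset(["c", "d"]) in clades:
                hits += 1
        assert hits >= 9

    def test_end_to_end_topology_recovery_from_simulated_data(self):
        tree = four_celltype_tree("e", overlap=0.9)
        target = {
            frozenset(["neutrophils", "monocytes"]),
            frozenset(["CD4", "CD8"]),
        }
        hits = 0
        n_runs = 5
        for seed in range(n_runs):
            config = SimulationConfig(
                n_features=2000, n_per_group=100, tree=tree, seed=300 + seed,
                dirichlet_alpha={"neutrophils": 27.94, "monocytes": 4.64, "CD8": 2.47, "CD4": 9.38},
            )
            bulk, props, truth = simulate_dataset(config)
            base = baseline_test(bulk, props, truth.design())
            topo = estimate_tree(base)
            if _nontrivial_clades(topo) == target:
                hits += 1
        assert hits >= 0.8 * n_runs


def _nontrivial_clades(topo):
    children: dict[str, list[str]] = {}
    for node, parent in topo.parent_map.items():
        if parent is not None:
            children.setdefault(parent, []).append(node)

    def leafset(node):
        kids = children.get(node, [])
        if not kids:
            return frozenset([node])
        return frozenset().union(*(leafset(c) for c in kids))

    all_leaves = frozenset(topo.leaf_labels)
    return {
        ls
        for node in children
        if 1 < len(ls := leafset(node)) < len(all_leaves)
    }


class TestEstimateNodePriors:
    # printed p-value fixture: 10 features x 3 cell types
    FIXTURE = np.array(
        [
            [0.001, 0.200, 0.900],
            [0.020, 0.030, 0.700],
            [0.500, 0.010, 0.800],
            [0.600, 0.700, 0.030],
            [0.040, 0.600, 0.020],
            [0.900, 0.950, 0.990],
            [0.030, 0.045, 0.600],
            [0.700, 0.800, 0.900],
            [0.049, 0.500, 0.700],
            [0.800, 0.049, 0.600],
        ]
    )

    def test_hand_counted_fractions(self):
        result = make_result(self.FIXTURE, ["a", "b", "c"])
        topo = single_layer_topology(["a", "b", "c"])
        est = estimate_node_priors(result, topo, threshold=0.05)
        # hand counts below the 0.05 threshold
        assert est.pi["a"] == pytest.approx(5 / 10)
        assert est.pi["b"] == pytest.approx(4 / 10)
        assert est.pi["c"] == pytest.approx(2 / 10)
        assert est.pi["root"] == pytest.approx(8 / 10)  # significant in any
        assert est.p["a"] == pytest.approx(0.5 / 0.8)

    def test_nested_topology_uses_min_over_leafset(self):
        result = make_result(self.FIXTURE, ["a", "b", "c"])
        pm = {"root": None, "ab": "root", "a": "ab", "b": "ab", "c": "root"}
        from cedar.estimation import TreeTopology

        topo = TreeTopology(parent_map=pm, leaf_labels=["a", "b", "c"])
        est = estimate_node_priors(result, topo, threshold=0.05)
        assert est.pi["ab"] == pytest.approx(7 / 10)  # min(a, b) < 0.05
        assert est.p["ab"] == pytest.approx(0.7 / 0.8)
        assert est.p["a"] == pytest.approx(0.5 / 0.7)

    def test_all_insignificant_clamps_to_floor(self):
        result = make_result(np.ones((50, 2)), ["a", "b"])
        topo = single_layer_topology(["a", "b"])
        with pytest.warns(UserWarning, match="CEDAR-W006"):
            est = estimate_node_priors(result, topo, threshold=0.05)
        assert est.pi["root"] == 0.0
        assert est.tree.root_pi == PROB_FLOOR

    def test_half_ratio(self):
        p = np.ones((100, 2))
        p[:5, 0] = 0.001  # leaf a significant in 5/100
        p[5:10, 1] = 0.001  # leaf b in another 5/100 -> parent 10/100
        est = estimate_node_priors(
            make_result(p, ["a", "b"]), single_layer_topology(["a", "b"]), 0.05
        )
        assert est.pi["root"] == pytest.approx(0.10)
        assert est.p["a"] == pytest.approx(0.5)

    def test_path_priors_are_nested(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=(300, 4))
        pm = {
            "root": None, "ab": "root", "abc": None,  # placeholder fixed below
        }
        pm = {
            "root": None, "abc": "root", "ab": "abc",
            "a": "ab", "b": "ab", "c": "abc", "d": "root",
        }
        from cedar.estimation import TreeTopology

        topo = TreeTopology(parent_map=pm, leaf_labels=["a", "b", "c", "d"])
        est = estimate_node_priors(make_result(p, list("abcd")), topo, 0.3)
        for node, parent in pm.items():
            if parent is not None:
                assert est.pi[node] <= est.pi[parent] + 1e-12


class TestProportionEstimation:
    def rng_reference(self, m=60, k=3, seed=5):
        rng = np.random.default_rng(seed)
        ref = pd.DataFrame(
            rng.lognormal(2.0, 0.8, size=(m, k)),
            index=[f"m{i}" for i in range(m)],
            columns=["a", "b", "c"],
        )
        props = rng.dirichlet(np.ones(k) * 4, size=20)
        return ref, props

    def test_noiseless_mixture_recovered_exactly(self):
        ref, props = self.rng_reference()
        y = ref.to_numpy() @ props.T
        bulk = BulkMatrix(
            values=y, feature_ids=list(ref.index),
            sample_ids=[f"s{i}" for i in range(20)],
        )
        est = estimate_proportions_rb(bulk, ref)
        np.testing.assert_allclose(est.values, props, atol=1e-8)

    def test_small_noise_small_error(self):
        ref, props = self.rng_reference(seed=6)
        rng = np.random.default_rng(7)
        y = ref.to_numpy() @ props.T
        y = y + rng.normal(scale=0.01 * y.mean(), size=y.shape)
        bulk = BulkMatrix(
            values=y, feature_ids=list(ref.index),
            sample_ids=[f"s{i}" for i in range(20)],
        )
        est = estimate_proportions_rb(bulk, ref)
        assert np.abs(est.values - props).mean() < 0.02

    def test_output_rows_are_simplex(self):
        ref, props = self.rng_reference(seed=8)
        rng = np.random.default_rng(9)
        y = ref.to_numpy() @ props.T + rng.normal(scale=1.0, size=(len(ref), 20))
        bulk = BulkMatrix(
            values=y, feature_ids=list(ref.index),
            sample_ids=[f"s{i}" for i in range(20)],
        )
        est = estimate_proportions_rb(bulk, ref)
        assert np.all(est.values >= 0)
        np.testing.assert_allclose(est.values.sum(axis=1), 1.0, atol=1e-12)

    def test_disjoint_features_rejected(self):
        ref, _ = self.rng_reference()
        bulk = BulkMatrix(
            values=np.ones((2, 3)), feature_ids=["x", "y"], sample_ids=["s1", "s2", "s3"]
        )
        with pytest.raises(ValueError, match="marker"):
            estimate_proportions_rb(bulk, ref)

    def test_collinear_reference_warns(self):
        rng = np.random.default_rng(12)
        col = rng.lognormal(2.0, 0.5, size=40)
        ref = pd.DataFrame(
            {"a": col, "b": 2 * col, "c": rng.lognormal(2.0, 0.5, size=40)},
            index=[f"m{i}" for i in range(40)],
        )
        bulk = BulkMatrix(
            values=ref.to_numpy() @ np.array([[0.3, 0.3, 0.4]]).T,
            feature_ids=list(ref.index),
            sample_ids=["s1"],
        )
        with pytest.warns(UserWarning, match="CEDAR-W007"):
            estimate_proportions_rb(bulk, ref)
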