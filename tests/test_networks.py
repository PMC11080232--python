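"""CLR, graphical lasso + StARS, modularity, assortativity, keystones, and
the microbe-only vs virus-microbe comparison."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rumivirome.networks import (
    EcologyNetwork,
    categorical_assortativity,
    clr_transform,
    compare_networks,
    fastgreedy_modularity,
    filter_network_nodes,
    graphical_lasso,
    infer_network_glasso,
    keystone_nodes,
    modularity_q,
    node_metrics,
    _adjacency,
    _default_lambda_path,
)
from rumivirome.simulate import (
    chain_precision,
    precision_truth_edges,
    simulate_network_abundances,
)

from conftest import make_table


class TestNodeFilters:
    def test_microbe_kept_at_002pct_in_60pct(self):
        counts = np.full((10, 2), 1000.0)
        counts[:, 0] = 0
        counts[:6, 0] = 0.0002 * 1000 / (1 - 0.0002)  # 0.02% of each sample
        tab = make_table(counts)
        keep, _ = filter_network_nodes(tab)
        assert "t0" in keep and "t1" in keep

    def test_viral_coverage_exactly_one_dropped(self):
        micro = make_table(np.full((4, 1), 100))
        viral = make_table(np.full((4, 2), 1.0), value_kind="trimmed_mean_coverage")
        viral.values.iloc[:, 1] = 1.5
        _, vkeep = filter_network_nodes(micro, viral)
        assert vkeep == ["t1"]  # strictly "exceeding 1"

    def test_seventy_percent_prevalence_variant(self):
        micro = make_table(np.full((10, 1), 100))
        viral = make_table(np.zeros((10, 1)), value_kind="trimmed_mean_coverage")
        viral.values.iloc[:6, 0] = 5.0  # 60% prevalence
        _, keep50 = filter_network_nodes(micro, viral, viral_prev=0.5)
        _, keep70 = filter_network_nodes(micro, viral, viral_prev=0.7)
        assert keep50 == ["t0"] and keep70 == []


class TestCLR:
    def test_constant_row_all_zeros(self):
        out = clr_transform(np.full((2, 5), 7.0))
        assert np.allclose(out, 0.0)

    def test_rows_sum_to_zero(self, rng):
        out = clr_transform(rng.integers(0, 100, size=(6, 9)))
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_two_part_ratio_depth_invariant(self):
        # taxa at ratio 4: clr difference = log(4) regardless of depth
        for depth in (100, 10_000):
            out = clr_transform(np.array([[0.8 * depth, 0.2 * depth]]), pseudocount=1e-9)
            assert out[0, 0] - out[0, 1] == pytest.approx(np.log(4), abs=1e-3)


class TestGraphicalLasso:
    def test_matches_sklearn_coordinate_descent(self, rng):
        # independent oracle: sklearn solves the same objective by a
        # different algorithm (block coordinate descent)
        from sklearn.covariance import graphical_lasso as sk_glasso

        X = rng.standard_normal((80, 7))
        S = np.cov(X, rowvar=False)
        mine = graphical_lasso(S, 0.15, tol=1e-7, max_iter=3000)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, theirs = sk_glasso(S, alpha=0.15, tol=1e-8, max_iter=800)
        assert np.abs(mine - theirs).max() < 5e-3

    def test_edges_shrink_monotonically_with_lambda(self, rng):
        X = rng.standard_normal((60, 10))
        S = np.cov(X, rowvar=False)
        lambdas = _default_lambda_path(S, n_lambda=12)
        counts = []
        theta = None
        for lam in lambdas:
            theta = graphical_lasso(S, lam, theta0=theta)
            counts.append(int(_adjacency(theta).sum()) // 2)
        # along DEcreasing lambda the edge set only grows
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_non_finite_rejected(self):
        S = np.eye(3)
        S[0, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            graphical_lasso(S, 0.1)


class TestInference:
    def test_same_seed_identical_edges(self):
        tab = simulate_network_abundances(chain_precision(12), 100, 20_000, seed=3)
        clr = clr_transform(tab.values.to_numpy())
        nets = [
            infer_network_glasso(clr, stars_subsamples=8, seed=9, node_names=tab.taxon_ids)
            for _ in range(2)
        ]
        assert nets[0].edges == nets[1].edges

    def test_null_near_empty(self):
        tab = simulate_network_abundances(np.eye(30), 500, 100_000, seed=5)
        clr = clr_transform(tab.values.to_numpy())
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = infer_network_glasso(clr, seed=6, node_names=tab.taxon_ids)
        assert len(net.edges) <= 2

    def test_increasing_lambda_path_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            infer_network_glasso(np.random.default_rng(0).standard_normal((30, 5)),
                                 lambda_path=[0.1, 0.2])


class TestGraphMetrics:
    def test_two_triangles_q_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part, q = fastgreedy_modularity(g)
        assert q == pytest.approx(0.5)
        assert len(set(part.values())) == 2

    def test_complete_graph_single_community(self):
        part, q = fastgreedy_modularity(nx.complete_graph(5))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(set(part.values())) == 1

    def test_q_at_least_singleton_partition(self, rng):
        g = nx.gnp_random_graph(25, 0.15, seed=4)
        if g.number_of_edges() == 0:
            return
        _, q = fastgreedy_modularity(g)
        singleton = {n: i for i, n in enumerate(g.nodes)}
        assert q >= modularity_q(g, singleton) - 1e-12
        assert -0.5 <= q < 1

    def test_edgeless_rejected(self):
        g = nx.empty_graph(4)
        with pytest.raises(ValueError, match="edgeless"):
            fastgreedy_modularity(g)

    def test_planted_two_block_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            g = nx.planted_partition_graph(2, 30, 0.3, 0.02, seed=seed)
            part, _ = fastgreedy_modularity(g)
            truth = [0] * 30 + [1] * 30
            pred = [part[i] for i in range(60)]
            aris.append(adjusted_rand_score(truth, pred))
        assert np.median(aris) > 0.9

    def test_star_center_betweenness(self):
        m = node_metrics(nx.star_graph(5))
        assert m.loc[0, "degree"] == 5
        assert m.loc[0, "betweenness"] == 10.0  # C(5,2) leaf pairs
        assert m.loc[1, "betweenness"] == 0.0

    def test_path_midpoint_betweenness(self):
        m = node_metrics(nx.path_graph(3))
        assert m.loc[1, "betweenness"] == 1.0


class TestAssortativity:
    def test_all_within_category_one(self):
        g = nx.Graph([(0, 1), (2, 3)])
        cat = {0: "a", 1: "a", 2: "b", 3: "b"}
        assert categorical_assortativity(g, cat) == pytest.approx(1.0)

    def test_complete_bipartite_minus_one(self):
        g = nx.complete_bipartite_graph(3, 5)
        cat = {n: ("x" if n < 3 else "y") for n in g.nodes}
        assert categorical_assortativity(g, cat) == pytest.approx(-1.0)

    def test_single_category_undefined(self):
        g = nx.Graph([(0, 1)])
        with pytest.warns(UserWarning, match="single-category"):
            assert np.isnan(categorical_assortativity(g, {0: "a", 1: "a"}))

    def test_category_shuffle_near_zero_mean(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        cats = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        vals = []
        nodes = list(g.nodes)
        for _ in range(200):
            perm = rng.permutation(cats)
            vals.append(categorical_assortativity(g, dict(zip(nodes, perm))))
        assert abs(np.mean(vals)) < 0.05


class TestKeystones:
    def test_strict_thresholds(self):
        m = pd.DataFrame(
            {"degree": [16, 15, 20], "betweenness": [20_000, 30_000, 14_000]},
            index=["hub", "deg_at_15", "btw_below"],
        )
        assert keystone_nodes(m) == {"hub"}

    def test_empty_graph_empty(self):
        m = pd.DataFrame({"degree": [], "betweenness": []})
        assert keystone_nodes(m) == set()


def _net_from_graph(g, node_types=None, cats=None):
    for n in g.nodes:
        g.nodes[n]["node_type"] = (node_types or {}).get(n, "microbe")
        g.nodes[n]["category"] = (cats or {}).get(n, "p1")
        g.nodes[n]["is_core"] = False
    return EcologyNetwork(graph=g)


class TestCompareNetworks:
    def test_identical_networks_null(self):
        g1 = nx.gnp_random_graph(20, 0.2, seed=1)
        g2 = g1.copy()
        rep = compare_networks(_net_from_graph(g1), _net_from_graph(g2))
        assert rep["paired_t"] == 0.0 and rep["p_one_tailed"] == 0.5

    def test_added_viral_nodes_raise_microbial_degree(self):
        rng = np.random.default_rng(8)
        micro = nx.gnp_random_graph(30, 0.1, seed=2)
        combined = micro.copy()
        types = {}
        for v in range(12):
            vid = f"virus{v}"
            combined.add_node(vid)
            types[vid] = "virus"
            for host in rng.choice(30, size=2, replace=False):
                combined.add_edge(vid, int(host))
        rep = compare_networks(_net_from_graph(micro), _net_from_graph(combined, types))
        assert rep["combined"]["mean_microbial_degree"] > rep["micro_only"]["mean_microbial_degree"]
        assert rep["p_one_tailed"] < 0.05

    def test_node_set_mismatch_rejected(self):
        g1 = nx.path_graph(3)
        g2 = nx.path_graph(4)
        with pytest.raises(ValueError, match="node sets differ"):
            compare_networks(_net_from_graph(g1), _net_from_graph(g2))
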