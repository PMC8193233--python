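"""Co-occurrence network construction, topology, null ensemble and keystones."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from peatnet import network as net
from peatnet.diversity import OtuTable

from conftest import toy_table


class TestFilterAbundant:
    def test_dominant_otu_retained(self):
        t = toy_table([[50, 1], [50, 1]])
        out = net.filter_abundant(t, 0.001)
        assert "o1" in out.otu_ids

    def test_absent_otu_removed(self):
        t = toy_table([[100, 0, 5], [100, 0, 5]])
        out = net.filter_abundant(t, 0.001)
        assert "o2" not in out.otu_ids

    def test_mean_rule_hand_oracle(self):
        # o2 relative abundances: 0.002, 0.0005, 0.0005 -> mean 0.001 (not > 0.001)
        # o3 relative abundances: 0.004, 0.002, 0.0 -> mean 0.002 (> 0.001)
        counts = np.array(
            [[1994, 2, 4], [1998.0, 1, 4], [1999, 1, 0]]
        ).astype(int)
        counts[1] = [1995, 1, 4]
        t = toy_table(counts)
        rel = t.relative_abundance()
        expected = set(rel.columns[rel.mean(axis=0) > 0.001])
        out = net.filter_abundant(t, 0.001, rule="mean")
        assert set(out.otu_ids) == expected

    def test_all_vs_any_rules(self):
        t = toy_table([[10, 990], [990, 10]])
        assert set(net.filter_abundant(t, 0.5, rule="any").otu_ids) == {"o1", "o2"}
        with pytest.raises(ValueError, match="no OTU passes"):
            net.filter_abundant(t, 0.5, rule="all")


class TestCorrelationScreen:
    def test_duplicated_columns_rho_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(8)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.random(8)})
        rho, p, q = net.correlation_screen(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_null_calibration(self):
        """Independent columns: ~1% of raw p-values fall below 0.01."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((30, 46)))
        df.columns = [f"c{i}" for i in range(46)]
        rho, p, q = net.correlation_screen(df)
        iu = np.triu_indices(46, 1)
        frac = float((p.to_numpy()[iu] < 0.01).mean())  # 1035 pairs
        assert 0.002 < frac < 0.025

    def test_six_sample_rank_oracle(self):
        x = [3.0, 1, 4, 1.5, 5, 9]
        y = [2.0, 7, 1, 8, 2.8, 1.8]
        df = pd.DataFrame({"x": x, "y": y})
        rho, _, _ = net.correlation_screen(df)
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(expected)

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((10, 3)), columns=["a", "b", "c"])
        df["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            rho, _, _ = net.correlation_screen(df)
        assert "c" not in rho.columns


def _matrices(entries, nodes):
    rho = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    q = pd.DataFrame(np.zeros((len(nodes), len(nodes))), index=nodes, columns=nodes)
    for (u, v), (r, qq) in entries.items():
        rho.loc[u, v] = rho.loc[v, u] = r
        q.loc[u, v] = q.loc[v, u] = qq
    return rho, q


class TestBuildNetwork:
    def test_threshold_boundaries(self):
        nodes = ["a", "b", "c", "d"]
        rho, q = _matrices(
            {("a", "b"): (0.71, 0.005),   # edge
             ("a", "c"): (0.70, 0.001),   # |rho| not strictly above -> no edge
             ("b", "c"): (0.90, 0.02),    # q fails -> no edge
             ("c", "d"): (-0.75, 0.001)}, # negative edge
            nodes,
        )
        g = net.build_network(rho, q).graph
        assert g.has_edge("a", "b")
        assert not g.has_edge("a", "c")
        assert not g.has_edge("b", "c")
        assert g.has_edge("c", "d")
        assert g.edges[("c", "d")]["sign"] == "-"

    def test_isolated_nodes_dropped_but_reported(self):
        nodes = ["a", "b", "z"]
        rho, q = _matrices({("a", "b"): (0.9, 0.001)}, nodes)
        cn = net.build_network(rho, q)
        assert "z" not in cn.graph
        assert cn.isolated_nodes == ["z"]

    def test_empty_edge_set_errors(self):
        nodes = ["a", "b"]
        rho, q = _matrices({("a", "b"): (0.5, 0.001)}, nodes)
        with pytest.raises(ValueError, match="no edge passes"):
            net.build_network(rho, q)

    def test_input_order_invariance(self):
        nodes = ["a", "b", "c"]
        rho, q = _matrices({("a", "b"): (0.8, 0.001), ("b", "c"): (0.9, 0.001)},
                           nodes)
        g1 = net.build_network(rho, q).graph
        perm = ["c", "a", "b"]
        g2 = net.build_network(rho.loc[perm, perm], q.loc[perm, perm]).graph
        assert set(g1.edges) == set(g2.edges)


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Betweenness by exhaustive simple-path enumeration (tiny graphs only)."""
    btw = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        L = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == L]
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            btw[v] += through / len(shortest)
    return btw


class TestNodeTopology:
    def _net(self, edges):
        g = nx.Graph(edges)
        for n in g:
            g.nodes[n]["kind"] = "otu"
        return net.CoNetwork(g, 0.7, 0.01)

    def test_path_graph(self):
        topo = net.node_topology(self._net([("a", "b"), ("b", "c")]))
        assert topo.loc["b", "betweenness"] == pytest.approx(1.0)
        assert topo.loc["a", "betweenness"] == 0.0

    def test_star_graph(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        topo = net.node_topology(self._net(edges))
        assert topo.loc["hub", "degree"] == 5
        assert all(topo.loc[f"leaf{i}", "betweenness"] == 0 for i in range(5))
        assert topo.loc["hub", "eigenvector"] == pytest.approx(1.0)

    def test_brandes_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            topo = net.node_topology(g)
            oracle = brute_force_betweenness(g)
            for v in g:
                assert topo.loc[v, "betweenness"] == pytest.approx(oracle[v])

    def test_degree_sum_is_twice_edges(self):
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        topo = net.node_topology(g)
        assert topo["degree"].sum() == 2 * g.number_of_edges()


class TestGraphTopology:
    def test_triangle(self):
        topo = net.graph_topology(nx.complete_graph(3))
        assert topo.graph_density == pytest.approx(1.0)
        assert topo.clustering_coefficient == pytest.approx(1.0)
        assert topo.diameter == 1

    def test_path_graph(self):
        topo = net.graph_topology(nx.path_graph(3))
        assert topo.avg_path_length == pytest.approx(4 / 3)
        assert topo.diameter == 2
        assert topo.graph_density == pytest.approx(2 / 3)

    def test_two_cliques_with_bridge_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        topo = net.graph_topology(g)
        assert topo.n_modules == 2
        assert topo.modularity > 0.3
        left = {topo.module_of[i] for i in range(4)}
        right = {topo.module_of[i] for i in range(4, 8)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_diameter_at_least_path_length(self):
        g = nx.gnm_random_graph(20, 35, seed=3)
        topo = net.graph_topology(g)
        assert topo.diameter >= topo.avg_path_length


class TestErNull:
    def test_exact_edge_count_every_rep(self):
        g = nx.gnm_random_graph(30, 60, seed=1)
        summary = net.er_null_ensemble(g, n_reps=100, seed=0,
                                       metrics=("avg_degree", "graph_density"))
        assert summary.metrics.loc["avg_degree", "mean"] == pytest.approx(4.0)
        assert summary.metrics.loc["avg_degree", "sd"] == 0.0
        assert summary.metrics.loc["graph_density", "observed"] == pytest.approx(
            summary.metrics.loc["graph_density", "mean"]
        )

    def test_modular_graph_high_modularity_z(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g.add_edge(0, 8)
        summary = net.er_null_ensemble(g, n_reps=200, seed=2,
                                       metrics=("modularity",))
        assert summary.metrics.loc["modularity", "z"] > 2

    def test_reproducible(self):
        g = nx.gnm_random_graph(20, 40, seed=4)
        a = net.er_null_ensemble(g, 100, seed=7, metrics=("clustering_coefficient",))
        b = net.er_null_ensemble(g, 100, seed=7, metrics=("clustering_coefficient",))
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_too_few_reps_rejected(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError, match="n_reps"):
            net.er_null_ensemble(g, n_reps=10, seed=0)


class TestPowerlaw:
    def test_exact_powerlaw_histogram(self):
        # degrees 1,2,4 with frequencies 16,4,1: freq = 16 * k^-2
        g = nx.havel_hakimi_graph([4] + [2] * 4 + [1] * 16)
        slope, r2 = net.degree_powerlaw_check(g)
        assert slope == pytest.approx(-2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_regular_graph_degenerate(self):
        with pytest.raises(ValueError, match="distinct"):
            net.degree_powerlaw_check(nx.cycle_graph(10))

    def test_scale_free_fits_better_than_er(self):
        ba = nx.barabasi_albert_graph(200, 2, seed=0)
        er = nx.gnm_random_graph(200, ba.number_of_edges(), seed=0)
        _, r2_ba = net.degree_powerlaw_check(ba)
        _, r2_er = net.degree_powerlaw_check(er)
        assert r2_ba > r2_er


class TestKeystones:
    def test_star_center_unique_keystone(self):
        g = nx.star_graph(6)
        topo = net.node_topology(g)
        top = net.keystones(topo, k=1)
        assert list(top.index) == [0]

    def test_path_middle_ranks_first(self):
        g = nx.path_graph(5)
        topo = net.node_topology(g)
        assert net.keystones(topo, k=1).index[0] == 2

    def test_tie_broken_by_degree(self):
        topo = pd.DataFrame(
            {"betweenness": [5.0, 5.0, 1.0], "degree": [2, 7, 9],
             "closeness": 0.0, "eigenvector": 0.0},
            index=["x", "y", "z"],
        )
        assert list(net.keystones(topo, k=2).index) == ["y", "x"]

    def test_env_nodes_excluded(self):
        g = nx.star_graph(4)
        topo = net.node_topology(g)
        kinds = {0: "env", 1: "otu", 2: "otu", 3: "otu", 4: "otu"}
        top = net.keystones(topo, k=2, node_kinds=kinds)
        assert 0 not in top.index

    def test_k_larger_than_nodes_warns(self):
        g = nx.path_graph(3)
        topo = net.node_topology(g)
        with pytest.warns(UserWarning, match="only 3"):
            out = net.keystones(topo, k=10)
        assert len(out) == 3
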