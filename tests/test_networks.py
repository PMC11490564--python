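import numpy as np
import pandas as pd
import pytest

from granuleco import synthetic
from granuleco.data_io import CountTable
from granuleco.networks import (
    ConsensusNetwork,
    bh_adjust,
    build_bipartite_core_network,
    build_consensus_network,
    consensus_network_from_table,
    detect_modules,
    module_dynamics,
    per_sample_network_stats,
    spearman_correlations,
)
import networkx as nx


def _table(counts, kingdom="prokaryote"):
    n, p = counts.shape
    return CountTable(
        [f"s{i:02d}" for i in range(n)], [f"x{j}" for j in range(p)], counts,
        kingdom=kingdom,
    )


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(1, 11)
        counts = np.column_stack([x, x * 3, x[::-1], np.full(10, 5)])
        rho, p = spearman_correlations(counts.astype(float))
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        assert np.isnan(rho[0, 3])  # constant column -> missing

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.random((20, 5))
        rho, _ = spearman_correlations(x)
        from scipy.stats import rankdata

        ranks = np.column_stack([rankdata(x[:, j]) for j in range(5)])
        manual = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(rho, manual, atol=1e-12)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_closed_form(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_definition_oracle(self, rng):
        p = rng.random(50) * 0.999 + 1e-6
        q = bh_adjust(p)
        order = np.argsort(p)
        manual = np.empty(50)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            k = 50 - rank_from_top
            prev = min(prev, p[idx] * 50 / k)
            manual[idx] = prev
        assert np.allclose(q, manual, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestConsensusRule:
    def _matrices(self, p, rho_val=0.0, r_val=0.0, q_val=1.0):
        rho = np.full((p, p), rho_val)
        r = np.full((p, p), r_val)
        q = np.full((p, p), q_val)
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(r, 1.0)
        np.fill_diagonal(q, 0.0)
        return rho, r, q

    def test_strong_spearman_weak_sparcc_is_no_edge(self):
        rho, r, q = self._matrices(3, rho_val=0.7, r_val=0.4, q_val=0.01)
        net = build_consensus_network(list("abc"), rho, r, q, q)
        assert net.n_edges == 0
        assert net.n_nodes == 3

    def test_weak_correlations_keep_nodes_drop_edges(self):
        rho, r, q = self._matrices(4, rho_val=0.5, r_val=0.5, q_val=0.001)
        net = build_consensus_network(list("abcd"), rho, r, q, q)
        assert net.n_edges == 0 and net.n_nodes == 4

    def test_sign_disagreement_dropped_with_warning(self):
        rho, r, q = self._matrices(2, rho_val=0.9, r_val=-0.9, q_val=0.001)
        with pytest.warns(UserWarning, match="sign"):
            net = build_consensus_network(list("ab"), rho, r, q, q)
        assert net.n_edges == 0

    def test_consensus_is_subset_of_single_method_sets(self, rng):
        p = 12
        rho = np.clip(rng.normal(0, 0.5, (p, p)), -1, 1)
        rho = (rho + rho.T) / 2
        r = np.clip(rho + rng.normal(0, 0.2, (p, p)), -1, 1)
        r = (r + r.T) / 2
        q1 = rng.random((p, p)) * 0.2
        q2 = rng.random((p, p)) * 0.2
        net = build_consensus_network([f"x{i}" for i in range(p)], rho, r, q1, q2)
        for u, v, d in net.graph.edges(data=True):
            assert abs(d["rho"]) > 0.6 and d["q_rho"] < 0.05
            assert abs(d["r_sparcc"]) > 0.6 and d["q_sparcc"] < 0.05

    def test_proportional_triple_yields_triangle_through_full_stack(self, rng):
        n = 100
        base = rng.lognormal(0, 0.4, (n, 12))
        base[:, 1] = base[:, 0] * 0.5
        base[:, 2] = base[:, 0] * 0.7
        counts = np.maximum((base / base.sum(1, keepdims=True) * 20000), 0).astype(int)
        counts += 1
        t = _table(counts)
        # small pair count: higher bootstrap resolution so BH can resolve
        net = consensus_network_from_table(
            t, seed=3, sparcc_kwargs=dict(n_boot=999)
        )
        assert net.graph.has_edge("x0", "x1")
        assert net.graph.has_edge("x0", "x2")
        assert net.graph.has_edge("x1", "x2")


class TestModules:
    def _net_from_edges(self, edges, nodes=None):
        g = nx.Graph()
        if nodes:
            g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_edge(u, v, weight=1.0, rho=0.9, r_sparcc=0.9, q_rho=0.01,
                       q_sparcc=0.01, sign=1)
        for n in g.nodes:
            g.nodes[n].setdefault("kingdom", "prokaryote")
            g.nodes[n].setdefault("abundance", 1.0)
        return ConsensusNetwork(g)

    def test_two_disjoint_triangles_are_two_modules(self):
        net = self._net_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
        )
        labels = detect_modules(net)
        assert len(set(labels.values())) == 2
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]

    def test_complete_graph_is_one_module(self):
        import itertools

        net = self._net_from_edges(list(itertools.combinations("abcde", 2)))
        labels = detect_modules(net)
        assert len(set(labels.values())) == 1

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = nx.Graph()
            for i in range(16):
                g.add_node(f"n{i}", kingdom="prokaryote", abundance=1.0)
            for i in range(16):
                for j in range(i + 1, 16):
                    same = (i < 8) == (j < 8)
                    pr = 0.9 if same else 0.05
                    if rng.random() < pr:
                        g.add_edge(f"n{i}", f"n{j}", weight=1.0)
            net = ConsensusNetwork(g)
            labels = detect_modules(net)
            got = [labels[f"n{i}"] for i in range(16)]
            truth = [0] * 8 + [1] * 8
            scores.append(adjusted_rand_score(truth, got))
        assert np.mean(np.array(scores) >= 0.99) >= 0.9

    def test_empty_network_gives_singletons_with_warning(self):
        net = self._net_from_edges([], nodes=["a", "b"])
        with pytest.warns(UserWarning):
            labels = detect_modules(net)
        assert len(set(labels.values())) == 2


class TestModuleDynamics:
    def test_completeness_and_abundance(self):
        g = nx.Graph()
        for n in ("x0", "x1", "x2", "x3"):
            g.add_node(n, kingdom="prokaryote", abundance=0.25)
        g.add_edge("x0", "x1", weight=1.0)
        g.add_edge("x2", "x3", weight=1.0)
        net = ConsensusNetwork(g)
        counts = np.array([[5, 5, 0, 0], [1, 0, 2, 2]])
        t = _table(counts)
        detect_modules(net, table=t)
        md = module_dynamics(net, t)
        m0 = net.modules["x0"]
        row = md[(md.module == m0) & (md.sample_id == "s00")].iloc[0]
        assert row.completeness == 1.0
        assert row.abundance == pytest.approx(1.0)
        row = md[(md.module == m0) & (md.sample_id == "s01")].iloc[0]
        assert row.completeness == 0.5
        assert row.abundance == pytest.approx(0.2)


class TestPerSampleStats:
    def _net(self, edges, nodes):
        g = nx.Graph()
        for n in nodes:
            g.add_node(n, kingdom="prokaryote", abundance=0.1)
        for u, v in edges:
            g.add_edge(u, v, weight=1.0)
        return ConsensusNetwork(g)

    def test_k4_density_and_clustering(self):
        import itertools

        nodes = ["x0", "x1", "x2", "x3"]
        net = self._net(list(itertools.combinations(nodes, 2)), nodes)
        t = _table(np.ones((1, 4), dtype=int))
        st = per_sample_network_stats(net, t)
        assert st.loc[0, "density"] == pytest.approx(1.0)
        assert st.loc[0, "clustering"] == pytest.approx(1.0)

    def test_path_density_and_clustering(self):
        nodes = ["x0", "x1", "x2", "x3"]
        net = self._net([("x0", "x1"), ("x1", "x2"), ("x2", "x3")], nodes)
        t = _table(np.ones((1, 4), dtype=int))
        st = per_sample_network_stats(net, t)
        assert st.loc[0, "density"] == pytest.approx(0.5)
        assert st.loc[0, "clustering"] == pytest.approx(0.0)

    def test_triangle_plus_edge_matches_triple_count_oracle(self):
        nodes = [f"x{i}" for i in range(5)]
        net = self._net(
            [("x0", "x1"), ("x1", "x2"), ("x0", "x2"), ("x3", "x4")], nodes
        )
        t = _table(np.ones((1, 5), dtype=int))
        st = per_sample_network_stats(net, t)
        assert st.loc[0, "density"] == pytest.approx(0.4)
        # 1 triangle, 3 connected triples centred in it -> transitivity 1
        assert st.loc[0, "clustering"] == pytest.approx(1.0)

    def test_tiny_subgraph_is_missing(self):
        nodes = ["x0", "x1"]
        net = self._net([("x0", "x1")], nodes)
        counts = np.array([[1, 0]])
        t = _table(counts)
        st = per_sample_network_stats(net, t)
        assert np.isnan(st.loc[0, "density"])


class TestBipartite:
    def test_within_kingdom_pairs_excluded_and_positive_only(self):
        ds = synthetic.simulate_reactor_series(synthetic.preset_scenario("coupled", seed=2))
        bip = build_bipartite_core_network(
            ds.prok_table, ds.euk_table, seed=4,
            sparcc_kwargs=dict(n_boot=30, n_inner=5),
        )
        for u, v, d in bip.graph.edges(data=True):
            assert {bip.graph.nodes[u]["kingdom"], bip.graph.nodes[v]["kingdom"]} == {
                "prokaryote", "eukaryote",
            }
            assert d["rho"] > 0 and d["r_sparcc"] > 0

    def test_mismatched_samples_rejected(self, rng):
        a = _table(rng.integers(1, 9, (12, 6)))
        b = CountTable(
            [f"z{i}" for i in range(12)], [f"e{j}" for j in range(6)],
            rng.integers(1, 9, (12, 6)), kingdom="eukaryote",
        )
        with pytest.raises(ValueError, match="sample"):
            build_bipartite_core_network(a, b)
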