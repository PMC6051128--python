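"""Similarity indices, edge splits and the sampled-AUC harness."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu

import epinetdyn as e
from epinetdyn.linkpred import _non_edges, _train_graph

from conftest import brute_force_index


class TestWorkedExamples:
    def test_common_neighbors(self, toy_graph):
        assert e.common_neighbors(toy_graph, 2, 5) == 2
        assert e.common_neighbors(toy_graph, 1, 3) == 1

    def test_resource_allocation(self, toy_graph):
        assert e.resource_allocation(toy_graph, 2, 5) == pytest.approx(1.0)
        assert e.resource_allocation(toy_graph, 3, 6) == pytest.approx(0.25)

    def test_adamic_adar_natural_log(self, toy_graph):
        assert e.adamic_adar(toy_graph, 2, 5) == pytest.approx(2.8854,
                                                              abs=1e-4)

    def test_sorenson(self, toy_graph):
        assert e.sorenson(toy_graph, 2, 5) == pytest.approx(2 / 3)


class TestIndexEdgeCases:
    def test_disjoint_components_score_zero(self):
        g = nx.Graph([(1, 2), (3, 4)])
        assert e.common_neighbors(g, 1, 3) == 0
        assert e.resource_allocation(g, 1, 3) == 0.0
        assert e.adamic_adar(g, 1, 3) == 0.0
        assert e.sorenson(g, 1, 3) == 0.0

    def test_star_leaves_ra(self):
        n = 6
        g = nx.star_graph(n - 1)  # hub 0, leaves 1..5
        assert e.resource_allocation(g, 1, 2) == pytest.approx(1 / (n - 1))

    def test_aa_single_common_neighbor_degree_three(self):
        g = nx.Graph([(1, 3), (2, 3), (3, 4)])
        assert e.adamic_adar(g, 1, 2) == pytest.approx(1 / np.log(3))

    def test_triangle_sorenson(self):
        g = nx.complete_graph([1, 2, 3])
        assert e.sorenson(g, 1, 2) == pytest.approx(0.5)

    def test_isolated_pair_sorenson_zero(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        assert e.sorenson(g, 1, 2) == 0.0

    def test_identical_or_unknown_nodes_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            e.common_neighbors(toy_graph, 2, 2)
        with pytest.raises(KeyError):
            e.resource_allocation(toy_graph, 1, 99)


class TestSimilarityMatrix:
    def test_ra_matrix_matches_pairwise(self, toy_graph):
        s, order = e.similarity_matrix(toy_graph, "RA")
        pos = {v: i for i, v in enumerate(order)}
        assert s[pos[2], pos[5]] == pytest.approx(1.0)
        assert s[pos[3], pos[6]] == pytest.approx(0.25)
        assert np.allclose(s, s.T) and np.allclose(np.diag(s), 0.0)

    def test_empty_graph_all_zero(self):
        g = nx.empty_graph(5)
        for ix in e.INDEX_NAMES:
            s, _ = e.similarity_matrix(g, ix)
            assert not s.any()

    def test_relabeling_permutes_consistently(self, toy_graph):
        mapping = {1: 4, 2: 6, 3: 1, 4: 2, 5: 3, 6: 5}
        h = nx.relabel_nodes(toy_graph, mapping)
        s_g, order_g = e.similarity_matrix(toy_graph, "RA")
        s_h, order_h = e.similarity_matrix(h, "RA")
        pos_h = {v: i for i, v in enumerate(order_h)}
        for a, ia in enumerate(order_g):
            for b, ib in enumerate(order_g):
                assert s_h[pos_h[mapping[ia]], pos_h[mapping[ib]]] == \
                    pytest.approx(s_g[a, b])

    def test_unknown_index_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            e.similarity_matrix(toy_graph, "Katz")

    def test_weighted_ra_variant(self):
        from epinetdyn.linkpred import weighted_resource_allocation

        g = nx.Graph()
        g.add_edge(1, 3, weight=0.5)
        g.add_edge(2, 3, weight=0.8)
        g.add_edge(3, 4, weight=0.2)
        # strength(3) = 1.5; S(1,2) = 0.5 * 0.8 / 1.5
        expect = 0.5 * 0.8 / 1.5
        assert weighted_resource_allocation(g, 1, 2) == pytest.approx(expect)
        s, order = e.similarity_matrix(g, "RA", weighted=True)
        pos = {v: i for i, v in enumerate(order)}
        assert s[pos[1], pos[2]] == pytest.approx(expect)
        # unit weights reduce the variant to plain RA
        h = nx.Graph([(1, 3), (2, 3), (3, 4)])
        assert weighted_resource_allocation(h, 1, 2) == pytest.approx(
            e.resource_allocation(h, 1, 2))
        with pytest.raises(ValueError):
            e.similarity_matrix(g, "CN", weighted=True)


class TestOracleEquivalence:
    @pytest.mark.parametrize("index_name", e.INDEX_NAMES)
    def test_matches_set_enumeration_on_random_graphs(self, index_name):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.2, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            s, order = e.similarity_matrix(g, index_name)
            pos = {v: i for i, v in enumerate(order)}
            for x in g.nodes():
                for y in g.nodes():
                    if x >= y:
                        continue
                    expect = brute_force_index(g, x, y, index_name)
                    assert s[pos[x], pos[y]] == pytest.approx(expect,
                                                              abs=1e-12)

    def test_dominance_relations(self):
        # every common neighbour has degree >= 2, so RA <= CN/2 and
        # AA <= CN/ln 2
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            cn, _ = e.similarity_matrix(g, "CN")
            ra, _ = e.similarity_matrix(g, "RA")
            aa, _ = e.similarity_matrix(g, "AA")
            assert (ra <= cn / 2 + 1e-12).all()
            assert (aa <= cn / np.log(2) + 1e-12).all()


class TestEdgeSplit:
    def test_partition_sizes(self):
        g = nx.gnm_random_graph(30, 100, seed=0)
        split = e.split_edges(g, 0.9, seed=1)
        assert len(split.train) == 90 and len(split.probe) == 10
        assert set(split.train) | set(split.probe) == \
            {tuple(sorted(ed)) for ed in g.edges()}
        assert not set(split.train) & set(split.probe)

    def test_seeded_determinism(self):
        g = nx.gnm_random_graph(20, 50, seed=0)
        assert e.split_edges(g, 0.8, seed=5) == e.split_edges(g, 0.8, seed=5)

    def test_ratio_bounds(self):
        g = nx.gnm_random_graph(10, 20, seed=0)
        with pytest.raises(ValueError):
            e.split_edges(g, 0.0, seed=0)
        with pytest.raises(ValueError):
            e.split_edges(g, 1.0, seed=0)

    def test_benchmark_enforces_95_percent_cap(self):
        g = {"g": nx.gnm_random_graph(10, 20, seed=0)}
        with pytest.raises(ValueError):
            e.benchmark(g, ratios=(0.96,), n_repetitions=2)


class TestAucScore:
    def test_all_tied_scores_give_exactly_half(self):
        # train graph is a single edge: every pair scores 0, all ties
        g = nx.Graph([(1, 2), (3, 4)])
        g.add_nodes_from([5, 6])
        split = e.EdgeSplit(train=((1, 2),), probe=((3, 4),), train_ratio=0.5)
        assert e.auc_score(g, split, "RA", 500, seed=0) == 0.5

    def test_perfectly_separable_gives_one(self):
        # probe edge (1,2) keeps two common neighbours in train; every
        # non-edge (those touching 5 or 6) scores 0
        g = nx.complete_graph([1, 2, 3, 4])
        g.add_nodes_from([5, 6])
        split = e.EdgeSplit(
            train=tuple(ed for ed in map(tuple, map(sorted, g.edges()))
                        if ed != (1, 2)),
            probe=((1, 2),), train_ratio=5 / 6,
        )
        assert e.auc_score(g, split, "CN", 500, seed=0) == 1.0

    def test_complete_graph_rejected(self):
        g = nx.complete_graph(5)
        split = e.split_edges(g, 0.8, seed=0)
        with pytest.raises(ValueError):
            e.auc_score(g, split, "CN")

    def test_sampled_matches_exact_rank_auc(self):
        # oracle: full-enumeration rank AUC via the Mann-Whitney U statistic
        g = e.generate_random_graph("erdos_renyi", 20, 5, seed=2)
        split = e.split_edges(g, 0.8, seed=1)
        nl = sorted(g.nodes())
        pos = {v: i for i, v in enumerate(nl)}
        s, _ = e.similarity_matrix(_train_graph(g, split), "RA", nl)
        ne = _non_edges(g, nl)
        probe_scores = np.array([s[pos[u], pos[v]] for u, v in split.probe])
        nonedge_scores = s[ne[:, 0], ne[:, 1]]
        u = mannwhitneyu(probe_scores, nonedge_scores,
                         alternative="two-sided").statistic
        exact = u / (len(probe_scores) * len(nonedge_scores))
        samples = [e.auc_score(g, split, "RA", 2000, seed=k)
                   for k in range(100)]
        se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        assert abs(np.mean(samples) - exact) < 3 * se

    def test_score_reversal_flips_auc(self):
        g = e.generate_random_graph("scale_free", 25, 4, seed=3)
        for seed in range(5):
            split = e.split_edges(g, 0.85, seed=seed)
            auc = e.auc_score(g, split, "RA", 4000, seed=seed)
            flipped = e.auc_score(g, split, "RA", 4000, seed=seed,
                                  score_transform=lambda s: -s)
            assert auc + flipped == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_auc_within_unit_interval(self, seed):
        g = nx.gnm_random_graph(12, 25, seed=7)
        split = e.split_edges(g, 0.8, seed=seed % 1000)
        auc = e.auc_score(g, split, "AA", 200, seed=seed)
        assert 0.0 <= auc <= 1.0


class TestBenchmark:
    def test_ratio_sweep_rows_and_determinism(self):
        g = {"sf": e.generate_random_graph("scale_free", 30, 4, seed=0)}
        ratios = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
        t1 = e.benchmark(g, ("RA",), ratios, n_repetitions=5, seed=3)
        t2 = e.benchmark(g, ("RA",), ratios, n_repetitions=5, seed=3)
        assert len(t1) == len(ratios)
        assert list(t1["train_ratio"]) == list(ratios)
        assert t1.equals(t2)
        assert ((t1["mean_auc"] >= 0) & (t1["mean_auc"] <= 1)).all()


class TestGraphIO:
    def test_edge_list_roundtrip(self, tmp_path):
        g = e.generate_random_graph("small_world", 12, 4, seed=0)
        path = tmp_path / "g.edges"
        e.write_edge_list(g, path)
        back = e.read_edge_list(path)
        assert set(map(frozenset, back.edges())) == \
            set(map(frozenset, g.edges()))

    def test_weighted_roundtrip_and_comments(self, tmp_path):
        path = tmp_path / "g.edges"
        path.write_text("# header\n1 2 0.5\n2 3 0.25\n3 3 1.0\n")
        g = e.read_edge_list(path)
        assert g[1][2]["weight"] == 0.5
        assert not g.has_edge(3, 3)

    def test_graph_from_adjacency(self):
        adj = np.array([[0.0, 0.4, 0.0],
                        [0.4, 0.0, 0.2],
                        [0.0, 0.2, 0.0]])
        g = e.graph_from_adjacency(adj)
        assert set(g.nodes()) == {1, 2, 3}
        assert g[1][2]["weight"] == pytest.approx(0.4)
        assert not g.has_edge(1, 3)
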