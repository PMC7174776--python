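"""Feature engineering: per-entity statistics, similarity graphs, centralities."""

import itertools

import numpy as np
import pytest

from hypermda.features import (
    FeatureConfig,
    assemble_pair_features,
    bipartite_centralities,
    block_columns,
    build_entity_graph,
    sample_negatives,
    type1_features,
    type2_features,
    type3_features,
)
from hypermda.io import AssociationMatrix, SimilarityMatrix

from conftest import random_association, random_similarity


# --- brute-force shortest-path centrality oracle (independent of networkx) ---

def _bfs_dists(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_force_centralities(nodes, edges):
    """Normalized betweenness and Wasserman-Faust closeness by enumeration."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    # betweenness: enumerate all shortest paths between every pair
    bt = {u: 0.0 for u in nodes}
    dists = {u: _bfs_dists(adj, u) for u in nodes}

    def count_paths(s, t):
        # returns (count of shortest s-t paths, count through each node)
        if t not in dists[s]:
            return 0, {}
        d = dists[s][t]
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in adj[u]:
                if dists[s].get(v) == len(path) and dists[v].get(t) == d - len(path):
                    extend(path + [v])

        extend([s])
        through = {u: 0 for u in nodes}
        for p in paths:
            for u in p[1:-1]:
                through[u] += 1
        return len(paths), through

    for s, t in itertools.combinations(nodes, 2):
        total, through = count_paths(s, t)
        if total == 0:
            continue
        for u in nodes:
            bt[u] += through.get(u, 0) / total
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1
    bt = {u: v / norm for u, v in bt.items()}
    # closeness with the Wasserman-Faust component scaling
    cl = {}
    for u in nodes:
        d = dists[u]
        reach = len(d) - 1
        if reach == 0:
            cl[u] = 0.0
        else:
            cl[u] = (reach / sum(v for v in d.values())) * (reach / (n - 1))
    return bt, cl


class TestEntityGraph:
    def test_constant_matrix_has_no_edges(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 1.0)
        g = build_entity_graph(SimilarityMatrix(vals, list("abcd")))
        assert g.graph.number_of_edges() == 0

    def test_single_high_pair(self):
        vals = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        g = build_entity_graph(SimilarityMatrix(vals, list("abc")))
        assert set(map(frozenset, g.graph.edges)) == {frozenset({"a", "b"})}

    def test_simple_undirected_no_self_loops(self):
        g = build_entity_graph(random_similarity(8, np.random.default_rng(0)))
        assert all(u != v for u, v in g.graph.edges)


class TestType1:
    def test_empty_association_row(self):
        A = AssociationMatrix(np.zeros((2, 3)), ["m0", "m1"], ["d0", "d1", "d2"])
        sim = random_similarity(2, np.random.default_rng(0), ["m0", "m1"])
        f = type1_features("m0", A, sim, FeatureConfig())
        assert f[0] == 0.0

    def test_histogram_of_all_ones(self):
        vals = np.ones((5, 5))
        sim = SimilarityMatrix(vals, [f"m{i}" for i in range(5)])
        A = AssociationMatrix(np.zeros((5, 2)), sim.ids, ["d0", "d1"])
        f = type1_features("m0", A, sim, FeatureConfig(hist_bins=5))
        np.testing.assert_array_equal(f[2:], [0, 0, 0, 0, 4])

    def test_histogram_partitions_other_entities(self):
        rng = np.random.default_rng(4)
        sim = random_similarity(9, rng)
        A = AssociationMatrix(np.zeros((9, 2)), sim.ids, ["d0", "d1"])
        f = type1_features(sim.ids[3], A, sim, FeatureConfig())
        assert f[2:].sum() == 8

    def test_unknown_entity_errors(self):
        A = AssociationMatrix(np.zeros((1, 1)), ["m0"], ["d0"])
        with pytest.raises(KeyError):
            type1_features("nope", A, SimilarityMatrix(np.eye(1), ["m0"]), FeatureConfig())


class TestType2:
    def test_isolated_node_zeros(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        sim = SimilarityMatrix(vals, list("abc"))
        g = build_entity_graph(sim)
        f = type2_features("a", g, sim, FeatureConfig(k_sim=2))
        assert f[0] == 0.0 and f[-2] == 0.0 and f[-1] == 0.0

    def test_star_center_betweenness(self):
        vals = np.array(
            [[1.0, 0.9, 0.9, 0.9],
             [0.9, 1.0, 0.1, 0.1],
             [0.9, 0.1, 1.0, 0.1],
             [0.9, 0.1, 0.1, 1.0]]
        )
        sim = SimilarityMatrix(vals, list("cxyz"))
        g = build_entity_graph(sim)
        f = type2_features("c", g, sim, FeatureConfig(k_sim=2))
        assert f[0] == 3.0
        assert f[-2] == pytest.approx(1.0)  # normalized betweenness of the hub

    def test_k_sim_padding_and_values(self):
        vals = np.full((4, 4), 0.3)
        np.fill_diagonal(vals, 1.0)
        sim = SimilarityMatrix(vals, list("abcd"))
        g = build_entity_graph(sim)
        f = type2_features("a", g, sim, FeatureConfig(k_sim=2))
        np.testing.assert_allclose(f[1:3], [0.3, 0.3])

    @pytest.mark.parametrize("seed", range(4))
    def test_centralities_match_brute_force(self, seed):
        sim = random_similarity(7, np.random.default_rng(seed))
        g = build_entity_graph(sim)
        bt, cl = brute_force_centralities(list(g.graph.nodes), list(g.graph.edges))
        for node in g.graph.nodes:
            assert g.betweenness[node] == pytest.approx(bt[node], abs=1e-10)
            assert g.closeness[node] == pytest.approx(cl[node], abs=1e-10)


class TestType3:
    def _toy(self):
        import networkx as nx

        from hypermda.features import EntityGraph

        A = AssociationMatrix(
            np.array([[1.0, 1.0], [0.0, 1.0]]), ["m0", "m1"], ["d0", "d1"]
        )
        gm = nx.Graph([("m0", "m1")])
        gd = nx.Graph([("d0", "d1")])
        return A, EntityGraph(gm, "MMS"), EntityGraph(gd, "DMS")

    def test_neighbor_association_counts(self):
        A, mg, dg = self._toy()
        f = type3_features(("m0", "d0"), A, mg, dg)
        # d0's neighbour is d1; m0 is associated with d1 -> m_d_nb = 1
        assert f[0] == 1.0
        # m0's neighbour is m1; m1 is not associated with d0 -> d_m_nb = 0
        assert f[1] == 0.0

    def test_bipartite_centralities_match_brute_force(self):
        A, mg, dg = self._toy()
        nodes = [("m", m) for m in A.mirna_ids] + [("d", d) for d in A.disease_ids]
        rows, cols = np.nonzero(A.values == 1)
        edges = [(("m", A.mirna_ids[i]), ("d", A.disease_ids[j])) for i, j in zip(rows, cols)]
        bt, cl = brute_force_centralities(nodes, edges)
        got_bt, got_cl = bipartite_centralities(A)
        for kind, name in nodes:
            assert got_bt[name] == pytest.approx(bt[(kind, name)], abs=1e-10)
            assert got_cl[name] == pytest.approx(cl[(kind, name)], abs=1e-10)

    def test_zero_matrix_centralities_all_zero(self):
        A = AssociationMatrix(np.zeros((2, 2)), ["m0", "m1"], ["d0", "d1"])
        _, mg, dg = self._toy()
        f = type3_features(("m0", "d0"), A, mg, dg)
        np.testing.assert_array_equal(f[2:], 0.0)

    def test_disease_without_neighbors(self):
        A, mg, _ = self._toy()
        dg = build_entity_graph(
            SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["d0", "d1"])
        )
        assert dg.graph.number_of_edges() == 0
        f = type3_features(("m0", "d0"), A, mg, dg)
        assert f[0] == 0.0


class TestAssemble:
    def _inputs(self, seed=0, nm=6, nd=5):
        rng = np.random.default_rng(seed)
        A = random_association(nm, nd, rng)
        MMS = random_similarity(nm, rng, A.mirna_ids)
        MMS.role = "MMS"
        DMS = random_similarity(nd, rng, A.disease_ids)
        DMS.role = "DMS"
        return A, MMS, DMS

    def test_default_feature_count_is_66(self):
        A, MMS, DMS = self._inputs()
        t = assemble_pair_features(A, MMS, DMS, FeatureConfig(), [("m0", "d0")])
        assert t.X.shape[1] == 66 == len(t.feature_names)

    def test_pure_function_of_inputs(self):
        A, MMS, DMS = self._inputs()
        pairs = [("m0", "d0"), ("m1", "d2"), ("m0", "d0")]
        t = assemble_pair_features(A, MMS, DMS, FeatureConfig(), pairs)
        np.testing.assert_array_equal(t.X[0], t.X[2])
        t2 = assemble_pair_features(A, MMS, DMS, FeatureConfig(), pairs)
        np.testing.assert_array_equal(t.X, t2.X)

    def test_no_non_finite_values(self):
        A, MMS, DMS = self._inputs(3)
        pairs = [(m, d) for m in A.mirna_ids[:3] for d in A.disease_ids[:3]]
        t = assemble_pair_features(A, MMS, DMS, FeatureConfig(), pairs)
        assert np.all(np.isfinite(t.X))

    def test_block_columns_select_prefixes(self):
        A, MMS, DMS = self._inputs()
        t = assemble_pair_features(A, MMS, DMS, FeatureConfig(), [("m0", "d0")])
        cols = block_columns(t.feature_names, ("type3",))
        assert len(cols) == 6 and all(c.startswith("type3.") for c in cols)
        sub = t.select_columns(cols)
        assert sub.X.shape == (1, 6)


class TestSampleNegatives:
    def test_count_and_disjoint_from_positives(self):
        A = random_association(10, 8, np.random.default_rng(1), density=0.3)
        neg = sample_negatives(A, 10, FeatureConfig(rng_seed=0))
        assert len(neg) == 10 and len(set(neg)) == 10
        for m, d in neg:
            assert A.values[A.mirna_ids.index(m), A.disease_ids.index(d)] == 0

    def test_seed_determinism_and_variation(self):
        A = random_association(30, 30, np.random.default_rng(2), density=0.1)
        a = sample_negatives(A, 20, FeatureConfig(rng_seed=5))
        b = sample_negatives(A, 20, FeatureConfig(rng_seed=5))
        c = sample_negatives(A, 20, FeatureConfig(rng_seed=6))
        assert a == b
        assert a != c

    def test_insufficient_zero_pairs_errors(self):
        A = AssociationMatrix(np.ones((2, 2)), ["m0", "m1"], ["d0", "d1"])
        with pytest.raises(ValueError, match="zero-entry"):
            sample_negatives(A, 1, FeatureConfig())
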