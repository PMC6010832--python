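import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from lekgraph.clustering import (
    cluster_leks_to_nodes,
    great_circle_distance_matrix,
)
from lekgraph.errors import ValidationError
from lekgraph.popgraph import (
    GraphFitParams,
    PopGraph,
    build_popgraph,
    conditional_genetic_distance,
    encode_multivariate,
    fit_conditional_graph,
    gower_covariance,
    minimum_spanning_tree,
    node_distance_matrix,
)
from lekgraph.simulate import (
    SimConfig,
    hub_recovery_config,
    panmixia_config,
    simulate_stepping_stone,
)

from _oracles import mst_total_weight_oracle, random_weighted_graph
from conftest import make_table


def _two_node_assignment(table):
    return cluster_leks_to_nodes(table, cut_km=15, min_node_size=1)


def _graph_from_edges(node_ids, edge_list):
    """PopGraph shell for the graph-algorithm operations."""
    import pandas as pd

    k = len(node_ids)
    edges = pd.DataFrame(edge_list, columns=["node_a", "node_b", "weight"])
    edges["pcorr"] = 0.5
    edges["deviance"] = 10.0
    eye = np.eye(k)
    return PopGraph(list(node_ids), eye * 0, eye, eye, eye, eye, edges, 0.0)


class TestEncoding:
    def _table(self):
        # one lek -> one node; three alleles present at locus L01
        return make_table([
            [(150, 152)],
            [(150, 150)],
            [(154, 154)],
        ])

    def test_heterozygote_half_each(self):
        t = self._table()
        nodes = _two_node_assignment(t)
        enc = encode_multivariate(t, nodes)
        assert enc.columns == [("L01", 150), ("L01", 152), ("L01", 154)]
        assert list(enc.matrix[0]) == [0.5, 0.5, 0.0]

    def test_homozygote_full_column(self):
        t = self._table()
        enc = encode_multivariate(t, _two_node_assignment(t))
        assert list(enc.matrix[1]) == [1.0, 0.0, 0.0]

    def test_missing_imputed_with_node_frequencies(self):
        t = make_table([
            [(150, 150)], [(150, 150)], [(150, 152)], [(0, 0)],
        ])
        enc = encode_multivariate(t, _two_node_assignment(t))
        # node frequencies from 3 typed samples: p(150)=5/6, p(152)=1/6
        assert enc.matrix[3] == pytest.approx([5 / 6, 1 / 6], abs=1e-12)

    def test_block_sums_to_one(self, rng):
        from conftest import random_table

        t = random_table(rng, n_samples=20, n_loci=3, missing_rate=0.2)
        nodes = cluster_leks_to_nodes(t, cut_km=1e5, min_node_size=1)
        enc = encode_multivariate(t, nodes)
        start = 0
        for locus in t.loci:
            width = sum(1 for l, _ in enc.columns if l == locus)
            block = enc.matrix[:, start:start + width]
            assert np.allclose(block.sum(axis=1), 1.0)
            start += width


class TestNodeDistance:
    def test_identical_mean_vectors_zero(self):
        t = make_table(
            [[(150, 152)], [(150, 152)]],
            lek_ids=["lekA", "lekB"],
            lons=[-110.0, -109.0],
        )
        nodes = _two_node_assignment(t)
        assert nodes.n_nodes == 2
        enc = encode_multivariate(t, nodes)
        D = node_distance_matrix(enc, nodes)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_unit_vectors(self):
        t = make_table(
            [[(150, 150)], [(152, 152)]],
            lek_ids=["lekA", "lekB"],
            lons=[-110.0, -109.0],
        )
        nodes = _two_node_assignment(t)
        enc = encode_multivariate(t, nodes)
        D = node_distance_matrix(enc, nodes)
        assert D[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_permutation_consistency(self, rng):
        from conftest import random_table

        t = random_table(rng, n_samples=24, n_loci=3, missing_rate=0.0, n_leks=4)
        nodes = cluster_leks_to_nodes(t, cut_km=15, min_node_size=1)
        enc = encode_multivariate(t, nodes)
        D = node_distance_matrix(enc, nodes)
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and np.allclose(np.diag(D), 0)


class TestGowerCovariance:
    def test_two_node_hand_algebra(self):
        d = 3.7
        C, R = gower_covariance(np.array([[0.0, d], [d, 0.0]]))
        assert C == pytest.approx(np.array([[d / 4, -d / 4], [-d / 4, d / 4]]))
        assert np.allclose(np.diag(R), 1.0)

    def test_row_sums_zero(self, rng):
        X = rng.normal(size=(6, 4))
        D = ((X[:, None] - X[None, :]) ** 2).sum(-1)
        C, R = gower_covariance(D)
        assert np.allclose(C.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(np.diag(R), 1.0)

    def test_zero_variance_node_named(self):
        # three collinear points with the middle at the centroid
        X = np.array([[0.0], [1.0], [2.0]])
        D = ((X[:, None] - X[None, :]) ** 2).sum(-1)
        with pytest.raises(ValidationError, match="NB"):
            gower_covariance(D, ["NA_", "NB", "NC"])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            gower_covariance(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestFitConditionalGraph:
    def test_identity_correlation_no_edges(self):
        R = np.eye(5)
        pg = fit_conditional_graph(R, R, list("abcde"))
        assert pg.n_edges == 0

    def test_three_node_chain_excludes_ac(self):
        R = np.array([
            [1.0, 0.5, 0.25],
            [0.5, 1.0, 0.5],
            [0.25, 0.5, 1.0],
        ])
        pg = fit_conditional_graph(R, R, ["A", "B", "C"],
                                   GraphFitParams(n_eff=100))
        pairs = {frozenset((r.node_a, r.node_b)) for r in pg.edges.itertuples()}
        assert frozenset(("A", "C")) not in pairs
        assert frozenset(("A", "B")) in pairs and frozenset(("B", "C")) in pairs
        # and rho_AC given B is exactly zero
        i, j = 0, 2
        assert pg.pcorr[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_deviance_threshold_two_nodes(self):
        # with two variables the partial correlation equals the correlation
        for rho, kept in ((0.196, True), (0.190, False)):
            R = np.array([[1.0, rho], [rho, 1.0]])
            pg = fit_conditional_graph(R, R, ["A", "B"], GraphFitParams(n_eff=100))
            assert (pg.n_edges == 1) is kept, rho
        # hand value: -100 ln(1 - 0.196^2) = 3.92 > 3.841
        assert -100 * np.log(1 - 0.196**2) == pytest.approx(3.9173, abs=1e-3)

    def test_pruning_monotone_in_alpha(self, rng):
        for _ in range(5):
            X = rng.normal(size=(40, 8))
            R = np.corrcoef(X, rowvar=False)
            strict = fit_conditional_graph(R, R, list("abcdefgh"),
                                           GraphFitParams(alpha=0.01, n_eff=40))
            loose = fit_conditional_graph(R, R, list("abcdefgh"),
                                          GraphFitParams(alpha=0.05, n_eff=40))
            s = {frozenset((r.node_a, r.node_b)) for r in strict.edges.itertuples()}
            l = {frozenset((r.node_a, r.node_b)) for r in loose.edges.itertuples()}
            assert s <= l

    def test_tolerance_gate(self):
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        pg = fit_conditional_graph(R, R, ["A", "B"],
                                   GraphFitParams(n_eff=100, tolerance=0.95))
        assert pg.n_edges == 0

    def test_ggm_null_calibration(self):
        """With R estimated from n iid standard-normal observations, the
        edge-exclusion test retains ~alpha of the k(k-1)/2 possible edges."""
        rng = np.random.default_rng(123)
        k, n, runs = 8, 200, 100
        total = 0
        for _ in range(runs):
            X = rng.normal(size=(n, k))
            R = np.corrcoef(X, rowvar=False)
            pg = fit_conditional_graph(R, R, [str(i) for i in range(k)],
                                       GraphFitParams(alpha=0.05, n_eff=n))
            total += pg.n_edges
        possible = runs * k * (k - 1) // 2
        rate = total / possible
        # binomial MC error: sd ~ sqrt(.05*.95/possible) ~ 0.004
        assert 0.03 < rate < 0.08

    def test_panmixia_retention_is_conservative_at_node_count_n_eff(self):
        """Under panmixia with the node-count deviance convention, retained
        edges stay at or below the binomial expectation (see ledger: exact
        binomial calibration is unattainable for the Gower pathway)."""
        total, possible = 0, 0
        for seed in range(5):
            g, _, _ = simulate_stepping_stone(panmixia_config(seed))
            nodes = cluster_leks_to_nodes(g)
            enc = encode_multivariate(g, nodes)
            D = node_distance_matrix(enc, nodes)
            C, R = gower_covariance(D, nodes.node_ids)
            pg = fit_conditional_graph(R, C, nodes.node_ids,
                                       GraphFitParams(n_eff=nodes.n_nodes))
            k = nodes.n_nodes
            total += pg.n_edges
            possible += k * (k - 1) // 2
            assert np.nanmax(np.abs(pg.pcorr[~np.eye(k, dtype=bool)])) < 0.9
        expect = 0.05 * possible
        assert total <= expect + 3 * np.sqrt(expect)


class TestMST:
    def test_triangle_keeps_two_lightest(self):
        pg = _graph_from_edges("abc", [("a", "b", 1.0), ("b", "c", 2.0),
                                       ("a", "c", 3.0)])
        mst = minimum_spanning_tree(pg)
        assert set(map(frozenset, mst.edges())) == {frozenset("ab"), frozenset("bc")}

    def test_tree_unchanged(self):
        pg = _graph_from_edges("abcd", [("a", "b", 1.0), ("b", "c", 2.0),
                                        ("c", "d", 0.5)])
        mst = minimum_spanning_tree(pg)
        assert mst.number_of_edges() == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_total_weight_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 7))
        nodes, edges = random_weighted_graph(rng, k, p=0.8)
        G = nx.Graph()
        G.add_nodes_from(nodes)
        G.add_weighted_edges_from(edges)
        if not nx.is_connected(G):
            pytest.skip("disconnected draw")
        mst = minimum_spanning_tree(G)
        got = sum(d["weight"] for _, _, d in mst.edges(data=True))
        assert got == pytest.approx(mst_total_weight_oracle(nodes, edges), abs=1e-9)


class TestConditionalGeneticDistance:
    def test_chain_adds_lengths(self):
        pg = _graph_from_edges("abc", [("a", "b", 2.0), ("b", "c", 3.0)])
        cgd = conditional_genetic_distance(pg)
        assert cgd.loc["a", "c"] == pytest.approx(5.0)

    def test_disconnected_pair_infinite(self):
        pg = _graph_from_edges("abc", [("a", "b", 2.0)])
        cgd = conditional_genetic_distance(pg)
        assert np.isinf(cgd.loc["a", "c"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_shortest_path(self, seed):
        from scipy.sparse.csgraph import shortest_path

        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(4, 9))
        nodes, edges = random_weighted_graph(rng, k, p=0.4)
        G = nx.Graph()
        G.add_nodes_from(nodes)
        G.add_weighted_edges_from(edges)
        cgd = conditional_genetic_distance(G)
        A = np.zeros((k, k))
        for u, v, w in edges:
            A[u, v] = A[v, u] = w
        ref = shortest_path(A, method="D", directed=False)
        assert np.allclose(cgd.values, ref, equal_nan=True)

    def test_triangle_inequality_and_zero_diagonal(self, rng):
        nodes, edges = random_weighted_graph(rng, 7, p=0.6)
        G = nx.Graph()
        G.add_nodes_from(nodes)
        G.add_weighted_edges_from(edges)
        cgd = conditional_genetic_distance(G).values
        assert np.allclose(np.diag(cgd), 0.0)
        finite = np.isfinite(cgd)
        for i, j, k2 in itertools.permutations(range(7), 3):
            if finite[i, j] and finite[j, k2] and finite[i, k2]:
                assert cgd[i, k2] <= cgd[i, j] + cgd[j, k2] + 1e-9


class TestEndToEnd:
    def test_mst_tracks_geography_on_stepping_stone(self):
        rs_values = []
        for seed in range(3):
            cfg = hub_recovery_config(seed)
            cfg.planted_hubs = {}
            g, _, _ = simulate_stepping_stone(cfg)
            nodes = cluster_leks_to_nodes(g)
            pg = build_popgraph(g, nodes)
            mst = minimum_spanning_tree(pg)
            lat, lon = nodes.centroid_array()
            geo = great_circle_distance_matrix(lat, lon)
            td = dict(nx.all_pairs_dijkstra_path_length(mst, weight="weight"))
            ids = nodes.node_ids
            xs, ys = [], []
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if ids[j] in td[ids[i]]:
                        xs.append(td[ids[i]][ids[j]])
                        ys.append(geo[i, j])
            rs_values.append(spearmanr(xs, ys).statistic)
        assert np.mean(rs_values) > 0.4

    def test_build_popgraph_defaults_n_eff_to_individuals(self):
        g, _, _ = simulate_stepping_stone(SimConfig(n_demes=4, seed=1))
        nodes = cluster_leks_to_nodes(g)
        pg = build_popgraph(g, nodes)
        assert pg.params.n_eff == g.n_samples
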