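"""Graph metrics against closed-form cases and brute-force oracles."""

import numpy as np
import pytest

from hofcnet import (
    BinaryGraph,
    SparsityCurve,
    SparsityGrid,
    auc_over_sparsity,
    binarize_over_grid,
    ConnectivityMatrix,
    global_graph_metrics,
    nodal_graph_metrics,
    normalize_small_world,
    rewire_null,
)
from conftest import random_binary_graph


# ---------------------------------------------------------------------------
# brute-force oracles (pure-python BFS / enumeration, independent of the
# implementation under test)
# ---------------------------------------------------------------------------

def bfs_distances(adj, source):
    n = adj.shape[0]
    dist = [None] * n
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] is None:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_global(adj):
    n = adj.shape[0]
    # clustering by triangle enumeration
    cs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nb) for b in nb[ai + 1:])
        cs.append(2.0 * links / (k * (k - 1)))
    cp = float(np.mean(cs))
    dists, invs = [], []
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if j == i:
                continue
            if d[j] is not None:
                dists.append(d[j])
                invs.append(1.0 / d[j])
            else:
                invs.append(0.0)
    lp = float(np.mean(dists)) if dists else 0.0
    eglob = float(np.sum(invs) / (n * (n - 1)))
    elocs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            elocs.append(0.0)
        else:
            sub = adj[np.ix_(nb, nb)]
            m = len(nb)
            acc = 0.0
            for a in range(m):
                d = bfs_distances(sub, a)
                for b in range(m):
                    if b != a and d[b] is not None:
                        acc += 1.0 / d[b]
            elocs.append(acc / (m * (m - 1)))
    return cp, lp, eglob, float(np.mean(elocs))


def oracle_betweenness(adj):
    """Unnormalized betweenness by explicit shortest-path counting."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        d = bfs_distances(adj, s)
        for v in range(n):
            if d[v] is not None:
                dist[s, v] = d[v]
        sigma[s, s] = 1.0
        order = sorted([v for v in range(n) if d[v] is not None], key=lambda v: d[v])
        for v in order:
            if v == s:
                continue
            sigma[s, v] = sum(
                sigma[s, u] for u in range(n) if adj[u, v] and dist[s, u] == dist[s, v] - 1
            )
    bc = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(n):
                if s == t or s == i or t == i or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, i] + dist[i, t] == dist[s, t] and sigma[s, t] > 0:
                    bc[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return bc / 2.0  # each unordered pair counted twice


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(adjacency=a, sparsity=len(edges) / (n * (n - 1) / 2))


class TestGlobalMetrics:
    def test_triangle(self):
        m = global_graph_metrics(graph_from_edges(3, [(0, 1), (1, 2), (0, 2)]))
        assert (m.Cp, m.Lp, m.Eglob, m.Eloc) == (1.0, 1.0, 1.0, 1.0)

    def test_path_graph(self):
        m = global_graph_metrics(graph_from_edges(3, [(0, 1), (1, 2)]))
        assert m.Cp == 0.0
        assert m.Lp == pytest.approx(4 / 3)
        assert m.Eglob == pytest.approx(5 / 6)

    def test_two_disjoint_edges(self):
        m = global_graph_metrics(graph_from_edges(4, [(0, 1), (2, 3)]))
        assert m.Eglob == pytest.approx(1 / 3)
        assert m.Lp == pytest.approx(1.0)  # connected pairs only

    def test_empty_graph_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty"):
            m = global_graph_metrics(graph_from_edges(4, []))
        assert (m.Cp, m.Lp, m.Eglob, m.Eloc) == (0.0, 0.0, 0.0, 0.0)

    def test_bruteforce_oracle_on_random_graphs(self):
        """Cp, Lp, Eglob, Eloc match BFS/triangle enumeration on 50 graphs."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 21))
            g = random_binary_graph(rng, n, float(rng.uniform(0.1, 0.6)))
            m = global_graph_metrics(g)
            cp, lp, eglob, eloc = oracle_global(g.adjacency)
            assert m.Cp == pytest.approx(cp, abs=1e-12)
            assert m.Lp == pytest.approx(lp, abs=1e-12)
            assert m.Eglob == pytest.approx(eglob, abs=1e-12)
            assert m.Eloc == pytest.approx(eloc, abs=1e-12)

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        g = random_binary_graph(rng, 12, 0.3)
        perm = rng.permutation(12)
        g2 = BinaryGraph(g.adjacency[np.ix_(perm, perm)], g.sparsity)
        m1, m2 = global_graph_metrics(g), global_graph_metrics(g2)
        for f in ("Cp", "Lp", "Eglob", "Eloc"):
            assert getattr(m1, f) == pytest.approx(getattr(m2, f), abs=1e-12)


class TestNodalMetrics:
    def test_star_graph(self):
        g = graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        m = nodal_graph_metrics(g)
        assert m.degree[0] == 4 and np.all(m.degree[1:] == 1)
        assert m.betweenness[0] == pytest.approx(6.0)  # (4*3)/2 leaf pairs
        assert np.all(m.betweenness[1:] == 0)
        assert m.efficiency[0] == pytest.approx(1.0)
        np.testing.assert_allclose(m.efficiency[1:], 0.625)  # (1 + 3*0.5)/4

    def test_complete_graph(self):
        g = graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        m = nodal_graph_metrics(g)
        assert np.all(m.betweenness == 0)
        np.testing.assert_allclose(m.efficiency, 1.0)
        assert m.degree.sum() == 2 * g.n_edges

    def test_betweenness_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = random_binary_graph(rng, 15, float(rng.uniform(0.15, 0.5)))
            m = nodal_graph_metrics(g)
            np.testing.assert_allclose(m.betweenness, oracle_betweenness(g.adjacency), atol=1e-9)

    def test_degree_sum_equals_twice_edge_count(self):
        rng = np.random.default_rng(14)
        g = random_binary_graph(rng, 18, 0.25)
        assert nodal_graph_metrics(g).degree.sum() == 2 * g.n_edges


class TestRewireNull:
    def test_degree_sequence_and_edge_count_preserved(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            g = random_binary_graph(rng, 16, 0.3)
            null = rewire_null(g, seed=int(rng.integers(2**31)))
            np.testing.assert_array_equal(
                null.adjacency.sum(axis=1), g.adjacency.sum(axis=1)
            )
            assert null.n_edges == g.n_edges

    def test_same_seed_same_result(self):
        rng = np.random.default_rng(21)
        g = random_binary_graph(rng, 16, 0.3)
        a = rewire_null(g, seed=5).adjacency
        b = rewire_null(g, seed=5).adjacency
        np.testing.assert_array_equal(a, b)

    def test_too_few_edges_returns_unchanged_with_warning(self):
        g = graph_from_edges(4, [(0, 1)])
        with pytest.warns(UserWarning, match="cannot rewire"):
            null = rewire_null(g, seed=0)
        np.testing.assert_array_equal(null.adjacency, g.adjacency)

    def test_null_clustering_matches_er_expectation(self):
        """Rewired nulls of an ER graph keep ER-level clustering (~p)."""
        rng = np.random.default_rng(22)
        g = random_binary_graph(rng, 30, 0.3)
        cps = [
            global_graph_metrics(rewire_null(g, seed=1000 + k)).Cp for k in range(100)
        ]
        assert abs(np.mean(cps) - 0.3) < 0.05


class TestSmallWorld:
    def test_identity_when_null_is_graph_itself(self):
        rng = np.random.default_rng(23)
        g = random_binary_graph(rng, 12, 0.4)
        with pytest.warns(UserWarning, match="no valid"):
            sw = normalize_small_world(g, n_null=1, n_swaps=0, seed=0)
        assert (sw.gamma, sw.lam, sw.sigma) == (1.0, 1.0, 1.0)

    def test_sigma_is_gamma_over_lambda(self):
        rng = np.random.default_rng(24)
        g = random_binary_graph(rng, 20, 0.3)
        sw = normalize_small_world(g, n_null=10, seed=1)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam, rel=1e-12)

    def test_watts_strogatz_lattice_is_small_world(self):
        """Ring lattice (30 nodes, k=4) with 5% shortcuts: sigma > 1."""
        import networkx as nx

        for seed in range(5):
            g_nx = nx.watts_strogatz_graph(30, 4, 0.05, seed=seed)
            adj = nx.to_numpy_array(g_nx).astype(np.uint8)
            g = BinaryGraph(adj, sparsity=g_nx.number_of_edges() / (30 * 29 / 2))
            sw = normalize_small_world(g, n_null=20, seed=seed)
            assert sw.sigma > 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_small_world(graph_from_edges(4, []), n_null=2, seed=0)


class TestAuc:
    def _curve(self, levels, values):
        return SparsityCurve(SparsityGrid(levels=levels), np.asarray(values, float), "m")

    def test_constant_curve(self):
        levels = np.round(np.arange(10, 51) / 100, 2)
        assert auc_over_sparsity(self._curve(levels, np.ones(41))) == pytest.approx(0.40)

    def test_identity_curve_closed_form(self):
        levels = np.round(np.arange(10, 51) / 100, 2)
        assert auc_over_sparsity(self._curve(levels, levels)) == pytest.approx(0.12)

    def test_hand_computed_trapezoid(self):
        levels = [0.1, 0.2, 0.3, 0.4, 0.5]
        values = [2.0, 1.0, 3.0, 0.5, 1.5]
        # trapezoid by hand: 0.1*(1.5 + 2.0 + 1.75 + 1.0) / 1
        expect = 0.1 * ((2 + 1) / 2 + (1 + 3) / 2 + (3 + 0.5) / 2 + (0.5 + 1.5) / 2)
        assert auc_over_sparsity(self._curve(levels, values)) == pytest.approx(expect)

    def test_non_finite_value_names_level(self):
        with pytest.raises(ValueError, match="0.2"):
            auc_over_sparsity(self._curve([0.1, 0.2, 0.3], [1.0, np.nan, 2.0]))

    def test_eglob_monotone_on_nested_graphs(self):
        rng = np.random.default_rng(30)
        v = rng.uniform(-1, 1, size=(20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        cm = ConnectivityMatrix(v, "low", [f"r{i}" for i in range(20)])
        grid = SparsityGrid(levels=np.round(np.arange(10, 51, 5) / 100, 2))
        eglobs = [global_graph_metrics(g).Eglob for g in binarize_over_grid(cm, grid)]
        assert np.all(np.diff(eglobs) >= -1e-12)
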