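"""Graph-topology metrics on binary brain networks.

Global metrics: clustering coefficient (Cp), characteristic path length
(Lp), global efficiency (Eglob) and local efficiency (Eloc). Small-world
normalization divides Cp and Lp by their means over degree-preserving
rewired null graphs, giving gamma, lambda and their ratio sigma
(small-worldness); sigma > 1 with gamma > 1 and lambda ~ 1 is the
small-world regime. Nodal metrics: degree, nodal efficiency and
(unnormalized) betweenness centrality.

Conventions on degenerate input: Lp averages over connected ordered pairs
only (infinite distances are excluded, keeping Lp finite on disconnected
graphs); Eglob treats disconnection as 1/inf = 0; nodes of degree < 2
contribute 0 to Cp and Eloc rather than being dropped from the mean.

Per-subject metric curves over the sparsity grid are summarized by the
trapezoidal area under the curve (AUC), the scalar used in group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .fc import BinaryGraph, SparsityGrid

__all__ = [
    "GlobalMetricsRaw",
    "SmallWorldMetrics",
    "NodalMetrics",
    "SparsityCurve",
    "global_graph_metrics",
    "nodal_graph_metrics",
    "rewire_null",
    "normalize_small_world",
    "auc_over_sparsity",
    "GLOBAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("gamma", "lambda", "sigma", "Lp", "Cp", "Eglob", "Eloc")


@dataclass(frozen=True)
class GlobalMetricsRaw:
    Cp: float
    Lp: float
    Eglob: float
    Eloc: float


@dataclass(frozen=True)
class SmallWorldMetrics:
    gamma: float
    lam: float
    sigma: float


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


@dataclass
class SparsityCurve:
    """A metric evaluated at each level of the sparsity grid."""

    grid: SparsityGrid
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("one value per sparsity level required")


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest paths.

    Dense graphs of <= a few hundred nodes: breadth-first search expressed
    as boolean matrix products (one product per distance level) beats the
    sparse-graph machinery by a wide margin at this size; larger graphs
    fall back to scipy's BFS.
    """
    n = adj.shape[0]
    if n > 256:
        return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    a = adj.astype(bool)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    reached = a | np.eye(n, dtype=bool)
    frontier = a
    k = 1
    while True:
        nxt = (frontier @ a) & ~reached
        if not nxt.any():
            break
        k += 1
        dist[nxt] = k
        reached |= nxt
        frontier = nxt
    return dist


def _bfs_sums(a: np.ndarray) -> tuple[float, float, int]:
    """(sum of 1/d, sum of d, count) over connected ordered pairs i != j.

    Accumulates level by level during the matrix-product BFS, so no
    distance matrix is materialized (the hot path for local efficiency).
    """
    n = a.shape[0]
    reached = a.copy()
    idx = np.arange(n)
    reached[idx, idx] = True
    frontier = a
    cnt = int(frontier.sum())
    inv_sum, dist_sum, total = float(cnt), float(cnt), cnt
    k = 1
    while True:
        nxt = (frontier @ a) & ~reached
        c = int(nxt.sum())
        if c == 0:
            break
        k += 1
        inv_sum += c / k
        dist_sum += c * k
        total += c
        reached |= nxt
        frontier = nxt
    return inv_sum, dist_sum, total


def _clustering_per_node(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(deg >= 2, 2.0 * tri / (deg * (deg - 1)), 0.0)
    return c


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    inv_sum, _, _ = _bfs_sums(adj.astype(bool))
    return inv_sum / (n * (n - 1))


def global_graph_metrics(g: BinaryGraph) -> GlobalMetricsRaw:
    """Cp, Lp, Eglob and Eloc of one binary graph.

    An empty graph yields all-zero metrics with a warning.
    """
    adj = g.adjacency
    n = adj.shape[0]
    if adj.sum() == 0:
        warnings.warn("empty graph: all global metrics set to 0", stacklevel=2)
        return GlobalMetricsRaw(0.0, 0.0, 0.0, 0.0)
    cp = float(_clustering_per_node(adj).mean())
    a_bool = adj.astype(bool)
    inv_sum, dist_sum, n_connected = _bfs_sums(a_bool)
    lp = dist_sum / n_connected if n_connected else 0.0
    eglob = inv_sum / (n * (n - 1))
    eloc_total = 0.0
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        m = nb.size
        if m >= 2:
            sub_inv, _, _ = _bfs_sums(a_bool[nb][:, nb])
            eloc_total += sub_inv / (m * (m - 1))
    return GlobalMetricsRaw(Cp=cp, Lp=lp, Eglob=eglob, Eloc=eloc_total / n)


def nodal_graph_metrics(g: BinaryGraph) -> NodalMetrics:
    """Per-node degree, nodal efficiency and unnormalized betweenness."""
    adj = g.adjacency
    n = adj.shape[0]
    deg = adj.sum(axis=1).astype(int)
    if n < 2:
        return NodalMetrics(deg, np.zeros(n), np.zeros(n))
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    graph = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(graph, normalized=False)
    betw = np.array([bc[i] for i in range(n)])
    return NodalMetrics(degree=deg, efficiency=eff, betweenness=betw)


def rewire_null(g: BinaryGraph, n_swaps: int | None = None, seed: int = 0) -> BinaryGraph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Picks two edges (a, b) and (c, d) and rewires them to (a, d), (c, b)
    whenever that creates neither self-loops nor multi-edges; the degree
    sequence is invariant by construction. Connectedness is not enforced.
    ``n_swaps`` defaults to 10x the edge count; attempts are capped at
    20x ``n_swaps``. Graphs admitting no swap are returned unchanged with
    a warning.
    """
    adj = g.adjacency
    edges = np.argwhere(np.triu(adj, k=1))
    m = edges.shape[0]
    if m < 2:
        warnings.warn("fewer than 2 edges: cannot rewire", stacklevel=2)
        return BinaryGraph(adj.copy(), g.sparsity, g.region_labels)
    if n_swaps is None:
        n_swaps = 10 * m
    rng = np.random.default_rng(seed)
    edge_set = {(int(i), int(j)) for i, j in edges}
    edge_list = [tuple(map(int, e)) for e in edges]
    swaps = 0
    attempts = 0
    max_attempts = 20 * n_swaps
    batch_k1 = batch_k2 = batch_flip = None
    pos = batch_size = 0
    while swaps < n_swaps and attempts < max_attempts:
        if pos >= batch_size:  # refill random draws in bulk
            batch_size = max(256, n_swaps - swaps)
            batch_k1 = rng.integers(0, m, size=batch_size)
            batch_k2 = rng.integers(0, m, size=batch_size)
            batch_flip = rng.integers(0, 2, size=batch_size)
            pos = 0
        k1, k2, flip = batch_k1[pos], batch_k2[pos], batch_flip[pos]
        pos += 1
        attempts += 1
        if k1 == k2:
            continue
        a, b = edge_list[k1]
        c, d = edge_list[k2]
        if flip:
            c, d = d, c
        if a == d or c == b:
            continue
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edge_list[k1])
        edge_set.discard(edge_list[k2])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[k1] = e1
        edge_list[k2] = e2
        swaps += 1
    if swaps == 0:
        warnings.warn("no valid double-edge swap found; returning graph unchanged", stacklevel=2)
        return BinaryGraph(adj.copy(), g.sparsity, g.region_labels)
    out = np.zeros_like(adj)
    idx = np.array(edge_list)
    out[idx[:, 0], idx[:, 1]] = 1
    out |= out.T
    return BinaryGraph(out, g.sparsity, g.region_labels)


def normalize_small_world(
    g: BinaryGraph,
    n_null: int = 100,
    n_swaps: int | None = None,
    seed: int = 0,
) -> SmallWorldMetrics:
    """gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda.

    The null ensemble is ``n_null`` degree-preserving rewirings of ``g``.
    """
    if g.n_edges == 0:
        raise ValueError("cannot normalize an empty graph")
    obs = global_graph_metrics(g)
    rng = np.random.default_rng(seed)
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for k in range(n_null):
        null = rewire_null(g, n_swaps=n_swaps, seed=int(rng.integers(2**31)))
        nm = global_graph_metrics(null)
        null_cp[k] = nm.Cp
        null_lp[k] = nm.Lp
    mean_cp, mean_lp = float(null_cp.mean()), float(null_lp.mean())
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("null ensemble has zero mean Cp or Lp; cannot normalize")
    gamma = obs.Cp / mean_cp
    lam = obs.Lp / mean_lp
    return SmallWorldMetrics(gamma=gamma, lam=lam, sigma=gamma / lam)


def auc_over_sparsity(curve: SparsityCurve) -> float:
    """Trapezoidal integral of a metric curve against sparsity."""
    if len(curve.grid) < 2:
        raise ValueError("AUC needs at least 2 sparsity levels")
    bad = np.flatnonzero(~np.isfinite(curve.values))
    if bad.size:
        levels = np.asarray(curve.grid.levels)[bad]
        raise ValueError(f"non-finite metric value(s) at sparsity level(s) {levels.tolist()}")
    return float(np.trapezoid(curve.values, curve.grid.levels))
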