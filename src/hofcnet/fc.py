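"""Functional-connectivity construction and sparsity thresholding.

Two network orders are supported. The low-order network (LOFC) connects two
regions by the Pearson correlation of their BOLD time series. The high-order
network (HOFC) connects two regions by the Pearson correlation of their LOFC
*profiles* — each region's vector of correlations to all other regions — so
it measures whether two regions attach to the rest of the brain in the same
way ("connectivity of connectivity").

Weighted matrices are reduced to binary graphs by discarding negative
weights and keeping the strongest positive edges down to a target sparsity
(fraction of the N(N-1)/2 possible edges retained), evaluated over a grid
of sparsity levels so that no single threshold drives group differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "BinaryGraph",
    "SparsityGrid",
    "compute_lofc",
    "compute_hofc",
    "binarize_at_sparsity",
    "binarize_over_grid",
]


@dataclass
class RoiTimeSeries:
    """One subject's T x N region time-series matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray of shape (T, N)
        One row per time point, one column per region. Arbitrary signal
        units; only correlations are ever computed from it.
    region_labels : list of str
        Region names, one per column, in column order.
    """

    subject_id: str
    data: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x N) array")
        t, n = self.data.shape
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} data columns"
            )
        if len(set(self.region_labels)) != n:
            raise ValueError("duplicate region labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")
        sd = self.data.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [self.region_labels[i] for i in flat]
            warnings.warn(f"zero-variance region(s): {names}", stacklevel=2)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """N x N symmetric weighted connectivity matrix (diagonal fixed at 0)."""

    values: np.ndarray
    order: str  # "low" | "high"
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if self.order not in ("low", "high"):
            raise ValueError(f"order must be 'low' or 'high', got {self.order!r}")
        if len(self.region_labels) != n:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix is not symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("off-diagonal entries outside [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.astype(bool)):
            raise ValueError("adjacency must be 0/1")
        a = a.astype(np.uint8)
        if np.any(np.diag(a)):
            raise ValueError("adjacency has nonzero diagonal")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency is not symmetric")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class SparsityGrid:
    """Ordered grid of sparsity levels; default 0.10 .. 0.50 step 0.01."""

    levels: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(10, 51) / 100.0, 2)
    )

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 1:
            raise ValueError("sparsity grid must be a non-empty 1-D sequence")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("sparsity levels must be strictly increasing")
        if self.levels[0] <= 0 or self.levels[-1] > 1:
            raise ValueError("sparsity levels must lie in (0, 1]")

    def __len__(self) -> int:
        return self.levels.size

    def __iter__(self):
        return iter(self.levels)


def compute_lofc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Low-order FC: Pearson correlation of region time series.

    Entry (i, j) is the Pearson correlation between the time series of
    regions i and j; the diagonal is set to 0 by convention.
    """
    sd = ts.data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [ts.region_labels[i] for i in flat]
        raise ValueError(f"cannot correlate zero-variance region(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, order="low", region_labels=list(ts.region_labels))


def compute_hofc(lofc: ConnectivityMatrix) -> ConnectivityMatrix:
    """High-order FC: Pearson correlation between LOFC profiles.

    For each region pair (i, j) the profiles are the i-th and j-th rows of
    the LOFC matrix restricted to the N-2 columns excluding i and j, so
    that neither the self-entry nor the mutual LOFC(i, j) entry feeds the
    correlation that is supposed to measure profile similarity. A constant
    profile yields an entry of 0 (with a warning) rather than NaN.
    """
    if lofc.order != "low":
        raise ValueError("compute_hofc expects a low-order matrix")
    n = lofc.n_regions
    if n < 4:
        raise ValueError(f"HOFC needs at least 4 regions (profiles of >= 2 entries), got {n}")
    v = lofc.values
    h = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            pi, pj = v[i, keep], v[j, keep]
            if pi.std() == 0 or pj.std() == 0:
                warned = True
                continue  # entry stays 0
            r = np.corrcoef(pi, pj)[0, 1]
            h[i, j] = h[j, i] = min(1.0, max(-1.0, r))
    if warned:
        warnings.warn("constant LOFC profile(s); affected HOFC entries set to 0", stacklevel=2)
    return ConnectivityMatrix(values=h, order="high", region_labels=list(lofc.region_labels))


def _target_edge_count(s: float, n: int) -> int:
    # half-up rounding; np.round would round halves to even
    return int(math.floor(s * n * (n - 1) / 2.0 + 0.5))


def binarize_at_sparsity(cm: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Threshold a weighted matrix to a binary graph at sparsity ``s``.

    Negative and zero weights are discarded; the surviving positive edges
    are ranked by weight (descending) and the strongest
    K = round(s * N(N-1)/2) become edges. Ties at the cut are broken by
    lexicographic (i, j) order for determinism. If fewer than K positive
    edges exist, all of them are kept and the achieved sparsity is warned
    about instead of raising.
    """
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    n = cm.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = cm.values[iu, ju]
    pos = w > 0
    k_target = _target_edge_count(s, n)
    order = np.lexsort((ju[pos], iu[pos], -w[pos]))  # weight desc, then (i, j)
    keep = order[:k_target]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[pos][keep], ju[pos][keep]] = 1
    adj |= adj.T
    g = BinaryGraph(adjacency=adj, sparsity=s, region_labels=list(cm.region_labels))
    if keep.size < k_target:
        achieved = keep.size / (n * (n - 1) / 2.0)
        warnings.warn(
            f"only {keep.size} positive edges available for target {k_target}; "
            f"achieved sparsity {achieved:.3f}",
            stacklevel=2,
        )
    return g


def binarize_over_grid(cm: ConnectivityMatrix, grid: SparsityGrid | None = None) -> list[BinaryGraph]:
    """Binarize at every level of the sparsity grid (default 41 levels)."""
    grid = grid if grid is not None else SparsityGrid()
    return [binarize_at_sparsity(cm, float(s)) for s in grid]
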