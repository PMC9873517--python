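"""Between-group and brain-behavior statistics.

Covers the inferential layer of the pipeline: covariate-adjusted
comparisons of per-subject network metrics (linear model with a 0/1 group
code; reduces exactly to the pooled two-sample t test with no covariates),
Benjamini-Hochberg FDR for nodal metrics, the network-based statistic
(NBS) for edge-level family-wise-error control, partial Spearman
correlations between metrics and clinical scores, and the demographic
tests used for cohort tables (summary-statistic t test, 2x2 chi-square,
Mann-Whitney U).

NBS: edge-wise adjusted group tests are thresholded at a primary alpha,
connected components are formed from the surviving edges, and the size
(extent, i.e. edge count; optionally intensity) of each observed component
is referred to the permutation null distribution of the maximum component
size under random relabeling of groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .fc import ConnectivityMatrix

__all__ = [
    "GroupComparison",
    "NbsResult",
    "CorrelationResult",
    "adjusted_group_test",
    "summary_t_test",
    "chi_square_2x2",
    "mann_whitney",
    "fdr_bh",
    "nbs",
    "partial_spearman",
]


@dataclass
class GroupComparison:
    metric_name: str
    t_stat: float
    p_value: float
    direction: int  # sign of group-B-minus-group-A effect
    adjusted_p: float | None = None


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class NbsResult:
    edges: list[tuple[int, int]]              # suprathreshold edges (index pairs)
    t_values: np.ndarray                       # edge-wise t over all unique edges
    components: list[dict] = field(default_factory=list)
    # each component: {"edges": [...], "nodes": [...], "size": float, "corrected_p": float}
    threshold: float = 0.0
    n_perm: int = 0
    null_max: np.ndarray | None = None
    region_labels: list[str] | None = None

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.components if c["corrected_p"] < alpha]


def _covariate_design(n: int, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["const"]
    x = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    return x, ["const", *covariates.columns.astype(str)]


def _check_collinear(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    # locate offending columns by incremental rank
    bad = []
    cols: list[int] = []
    for k in range(x.shape[1]):
        trial = x[:, cols + [k]]
        if np.linalg.matrix_rank(trial) == len(cols) + 1:
            cols.append(k)
        else:
            bad.append(names[k])
    raise ValueError(f"collinear design columns: {bad}")


def adjusted_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | None = None,
    metric_name: str = "",
) -> GroupComparison:
    """Group comparison of one per-subject metric, adjusting for covariates.

    Fits value ~ group + covariates by OLS with group coded 0 (first label
    encountered, "group A") / 1 and reports the group coefficient's t
    statistic with a two-sided p. With no covariates this is exactly the
    pooled two-sample t test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels.tolist()}")
    g = (groups == labels[1]).astype(float)
    if min(g.sum(), (1 - g).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing or non-finite metric values")
    z, names = _covariate_design(values.size, covariates)
    x = np.column_stack([z[:, :1], g, z[:, 1:]])
    _check_collinear(x, [names[0], "group", *names[1:]])
    fit = sm.OLS(values, x).fit()
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    if values.std() == 0:  # identical values: define t=0, p=1 (zero-variance model)
        t, p = 0.0, 1.0
    return GroupComparison(
        metric_name=metric_name,
        t_stat=t,
        p_value=p,
        direction=int(np.sign(fit.params[1])),
    )


def summary_t_test(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics (df = n_a + n_b - 2)."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, df = 1) on a 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column total is 0")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return r1 - x.size * (x.size + 1) / 2.0


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U rank-sum test, two-sided.

    Returns (U of the first sample, p). For small samples
    (n_a + n_b <= 20) p is exact by full enumeration of group assignments,
    which is valid under ties; otherwise the normal approximation with tie
    correction is used.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least one value")
    u = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    if n1 + n2 <= 20:
        pooled = np.concatenate([x, y])
        obs_dev = abs(u - mu)
        count = 0
        total = comb(n1 + n2, n1)
        idx = np.arange(n1 + n2)
        for pick in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
        return float(u), count / total
    # asymptotic with tie correction
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return float(u), 1.0
    z = (u - mu) / np.sqrt(var)
    return float(u), float(2.0 * sps.norm.sf(abs(z)))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


# ---------------------------------------------------------------------------
# network-based statistic
# ---------------------------------------------------------------------------

def _residualize(z_pinv: np.ndarray, z: np.ndarray, v: np.ndarray) -> np.ndarray:
    return v - z @ (z_pinv @ v)

def _edgewise_t(r_y: np.ndarray, r_g: np.ndarray, df: int) -> np.ndarray:
    """Group-coefficient t per edge from covariate-residualized data (Frisch-Waugh)."""
    gg = float(r_g @ r_g)
    beta = (r_g @ r_y) / gg
    rss = (r_y**2).sum(axis=0) - beta**2 * gg
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / gg)
    t[~np.isfinite(t)] = 0.0
    return t


def _max_component_size(
    iu: np.ndarray, ju: np.ndarray, supra: np.ndarray, n: int,
    t_abs: np.ndarray, threshold: float, intensity: bool,
) -> float:
    if not supra.any():
        return 0.0
    si, sj = iu[supra], ju[supra]
    g = coo_matrix((np.ones(si.size), (si, sj)), shape=(n, n))
    _, labels = connected_components(g + g.T, directed=False)
    comp_of_edge = labels[si]
    if intensity:
        w = t_abs[supra] - threshold
        return float(np.bincount(comp_of_edge, weights=w).max())
    return float(np.bincount(comp_of_edge).max())


def nbs(
    matrices_a: list[ConnectivityMatrix],
    matrices_b: list[ConnectivityMatrix],
    covariates: pd.DataFrame | None = None,
    primary_alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "extent",
) -> NbsResult:
    """Network-based statistic with covariate-adjusted edge tests.

    1. every unique edge gets the adjusted group test (two-sided);
    2. edges with p < primary_alpha form the suprathreshold set;
    3. its connected components are scored by extent (edge count) or
       intensity (summed suprathreshold |t| excess);
    4. group labels are permuted ``n_perm`` times (covariates kept as-is)
       to build the null distribution of the maximum component score;
       corrected_p = (1 + #{null max >= observed}) / (n_perm + 1).

    No suprathreshold edge yields an empty (not erroneous) result.
    """
    if statistic not in ("extent", "intensity"):
        raise ValueError("statistic must be 'extent' or 'intensity'")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = matrices_a[0].region_labels
    for cm in [*matrices_a, *matrices_b]:
        if cm.region_labels != labels:
            raise ValueError("all matrices must share identical region labels")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    y = np.stack([cm.values[iu, ju] for cm in [*matrices_a, *matrices_b]])
    g = np.concatenate([np.zeros(len(matrices_a)), np.ones(len(matrices_b))])
    n_sub = g.size
    z, znames = _covariate_design(n_sub, covariates)
    _check_collinear(np.column_stack([z[:, :1], g, z[:, 1:]]), [znames[0], "group", *znames[1:]])
    z_pinv = np.linalg.pinv(z)
    df = n_sub - z.shape[1] - 1
    r_y = _residualize(z_pinv, z, y)
    r_g = _residualize(z_pinv, z, g)
    t_obs = _edgewise_t(r_y, r_g, df)
    t_crit = sps.t.ppf(1.0 - primary_alpha / 2.0, df)
    t_abs = np.abs(t_obs)
    supra = t_abs > t_crit
    intensity = statistic == "intensity"

    result = NbsResult(
        edges=[(int(i), int(j)) for i, j in zip(iu[supra], ju[supra])],
        t_values=t_obs,
        threshold=float(t_crit),
        n_perm=n_perm,
        region_labels=list(labels),
    )
    if not supra.any():
        result.null_max = np.zeros(n_perm)
        return result

    # observed components
    si, sj = iu[supra], ju[supra]
    gmat = coo_matrix((np.ones(si.size), (si, sj)), shape=(n, n))
    _, comp_labels = connected_components(gmat + gmat.T, directed=False)
    comp_of_edge = comp_labels[si]
    comps: list[dict] = []
    for cid in np.unique(comp_of_edge):
        mask = comp_of_edge == cid
        ce = [(int(a), int(b)) for a, b in zip(si[mask], sj[mask])]
        nodes = sorted({v for e in ce for v in e})
        if intensity:
            size = float((t_abs[supra][mask] - t_crit).sum())
        else:
            size = float(mask.sum())
        comps.append({"edges": ce, "nodes": nodes, "size": size, "corrected_p": 1.0})

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        g_perm = rng.permutation(g)
        r_gp = _residualize(z_pinv, z, g_perm)
        t_perm = np.abs(_edgewise_t(r_y, r_gp, df))
        null_max[k] = _max_component_size(
            iu, ju, t_perm > t_crit, n, t_perm, t_crit, intensity
        )
    for c in comps:
        c["corrected_p"] = float((1 + (null_max >= c["size"]).sum()) / (n_perm + 1))
    result.components = sorted(comps, key=lambda c: -c["size"])
    result.null_max = null_max
    return result


def partial_spearman(
    x, y, covariates: pd.DataFrame | None = None
) -> CorrelationResult:
    """Spearman correlation of x and y, partialling covariates out of the ranks.

    x, y and the covariates are rank-transformed; the ranks of x and y are
    residualized on the covariate ranks by linear regression and the
    residuals are Pearson-correlated; p uses the t approximation with
    df = n - 2 - n_covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant x or y")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if covariates is not None and covariates.shape[1] > 0:
        covariates = covariates.apply(lambda c: sps.rankdata(c.to_numpy(dtype=float)))
    z, _ = _covariate_design(n, covariates)
    z_pinv = np.linalg.pinv(z)
    ex = _residualize(z_pinv, z, rx)
    ey = _residualize(z_pinv, z, ry)
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        raise ValueError("residual ranks are constant after adjustment")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    k = 0 if covariates is None else covariates.shape[1]
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    if abs(rho) == 1.0:
        return CorrelationResult(rho=rho, p_value=0.0, n=n)
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(rho=rho, p_value=p, n=n)
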