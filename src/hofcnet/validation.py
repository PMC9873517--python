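"""Self-validation experiments: calibration, recovery and sanity studies.

These functions define the package's standard verification conditions —
scaled-down synthetic cohorts on which the inferential machinery can be
exercised end to end in minutes on one CPU:

* type-I calibration of NBS and of the global-AUC group tests under a
  zero-effect design (both populations identical);
* power/recovery of a planted 6-edge within-module effect by NBS and of
  the corresponding intra-modular FC reduction;
* the small-world normalization regime on reference graph families
  (Erdos-Renyi: gamma ~ 1, lambda ~ 1; Watts-Strogatz lattices with
  shortcuts: sigma > 1);
* classification sanity (separable cohort -> AUC 1; shuffled labels ->
  AUC ~ 0.5).

Conditions are deliberately smaller than a real fMRI study (20-30 regions
rather than 90, hundreds rather than ten thousand permutations, a thinned
sparsity grid and a shallow null ensemble): type-I error and recovery
rates are insensitive to these sizes, while runtimes drop by orders of
magnitude. The same functions back the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .classify import FeatureMatrix, build_features, svm_loocv
from .cohort import CohortDesign, EffectSpec, generate_cohort
from .fc import BinaryGraph, ConnectivityMatrix, SparsityGrid, binarize_at_sparsity, compute_lofc
from .modular import ModulePartition, intra_modular_fc
from .stats import adjusted_group_test, nbs
from .topology import SparsityCurve, auc_over_sparsity, global_graph_metrics, normalize_small_world

__all__ = [
    "even_partition",
    "table1_statistics",
    "er_small_world",
    "ws_small_world",
    "nbs_fwe_calibration",
    "global_auc_calibration",
    "planted_effect_recovery",
    "classification_sanity",
]

# reduced sparsity grid used by the calibration studies: 0.10-0.50 step 0.05
REDUCED_GRID = SparsityGrid(levels=np.round(np.arange(10, 51, 5) / 100.0, 2))


def even_partition(n_regions: int) -> dict[str, str]:
    """Regions split evenly over the five canonical modules."""
    modules = ("SMN", "DMN", "FPN", "VN", "SN")
    per = n_regions // len(modules)
    if per * len(modules) != n_regions:
        raise ValueError("n_regions must be a multiple of 5")
    return {f"r{i:02d}": modules[i // per] for i in range(n_regions)}


def table1_statistics() -> dict[str, float]:
    """Demographic test statistics from the study's printed cohort summaries."""
    from .stats import chi_square_2x2, summary_t_test

    t_age, p_age = summary_t_test(61.63, 6.39, 60, 60.69, 11.71, 51)
    chi2_sex, p_sex = chi_square_2x2(35, 25, 31, 20)
    return {"age_t": t_age, "age_p": p_age, "sex_chi2": chi2_sex, "sex_p": p_sex}


def _er_graph(rng: np.random.Generator, n: int, p: float) -> BinaryGraph:
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, k=1)
    a = a + a.T
    return BinaryGraph(a, sparsity=float(a.sum() / (n * (n - 1))))


def er_small_world(n_seeds: int = 20, seed: int = 0) -> dict[str, np.ndarray]:
    """gamma and lambda of dense ER graphs (30 nodes, p = 0.5); both ~ 1."""
    rng = np.random.default_rng(seed)
    gammas, lams = [], []
    for _ in range(n_seeds):
        g = _er_graph(rng, 30, 0.5)
        sw = normalize_small_world(g, n_null=20, seed=int(rng.integers(2**31)))
        gammas.append(sw.gamma)
        lams.append(sw.lam)
    return {"gamma": np.array(gammas), "lambda": np.array(lams)}


def ws_small_world(n_seeds: int = 20, seed: int = 0) -> np.ndarray:
    """sigma of Watts-Strogatz lattices (30 nodes, k = 4, 5% shortcuts); all > 1."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    sigmas = []
    for _ in range(n_seeds):
        g_nx = nx.watts_strogatz_graph(30, 4, 0.05, seed=int(rng.integers(2**31)))
        adj = nx.to_numpy_array(g_nx).astype(np.uint8)
        g = BinaryGraph(adj, sparsity=g_nx.number_of_edges() / (30 * 29 / 2))
        sw = normalize_small_world(g, n_null=20, seed=int(rng.integers(2**31)))
        sigmas.append(sw.sigma)
    return np.array(sigmas)


def _null_design(seed: int, n_regions: int = 20, n_timepoints: int = 100) -> CohortDesign:
    return CohortDesign(
        n_group_a=30, n_group_b=30, n_regions=n_regions,
        n_timepoints=n_timepoints, partition=even_partition(n_regions), seed=seed,
    )


def _lofc_by_group(design: CohortDesign) -> tuple[list[ConnectivityMatrix], list[ConnectivityMatrix]]:
    subs, _ = generate_cohort(design)
    a = [compute_lofc(ts) for ts, g in subs if g == "A"]
    b = [compute_lofc(ts) for ts, g in subs if g == "B"]
    return a, b


def nbs_fwe_calibration(n_cohorts: int = 200, n_perm: int = 500, seed: int = 0) -> float:
    """Family-wise error of NBS under the null: fraction of zero-effect
    cohorts (30+30 subjects, 20 regions) with any component at corrected
    p < 0.05. Should sit near the nominal 5%."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        a, b = _lofc_by_group(_null_design(int(rng.integers(2**31))))
        res = nbs(a, b, n_perm=n_perm, seed=int(rng.integers(2**31)))
        hits += bool(res.significant(0.05))
    return hits / n_cohorts


def _global_aucs(cm: ConnectivityMatrix, n_null: int, seed: int) -> dict[str, float]:
    per_metric: dict[str, list[float]] = {m: [] for m in
                                          ("gamma", "lambda", "sigma", "Lp", "Cp", "Eglob", "Eloc")}
    rng = np.random.default_rng(seed)
    for s in REDUCED_GRID:
        g = binarize_at_sparsity(cm, float(s))
        raw = global_graph_metrics(g)
        sw = normalize_small_world(g, n_null=n_null, n_swaps=g.n_edges,
                                   seed=int(rng.integers(2**31)))
        for name, v in (("gamma", sw.gamma), ("lambda", sw.lam), ("sigma", sw.sigma),
                        ("Lp", raw.Lp), ("Cp", raw.Cp), ("Eglob", raw.Eglob),
                        ("Eloc", raw.Eloc)):
            per_metric[name].append(v)
    return {m: auc_over_sparsity(SparsityCurve(REDUCED_GRID, np.array(v), m))
            for m, v in per_metric.items()}


def global_auc_calibration(n_cohorts: int = 100, n_null: int = 3, seed: int = 0) -> float:
    """Type-I error of the global-metric AUC group tests under the null.

    Zero-effect cohorts of 30+30 subjects and 30 regions (the denser
    30-region networks keep the rewired null ensembles non-degenerate at
    the lowest grid level); returns the fraction of the 7 metrics x
    n_cohorts tests rejected at p < 0.05."""
    rng = np.random.default_rng(seed)
    rejections, total = 0, 0
    groups = np.array(["A"] * 30 + ["B"] * 30)
    for _ in range(n_cohorts):
        design = _null_design(int(rng.integers(2**31)), n_regions=30)
        subs, _ = generate_cohort(design)
        aucs: dict[str, list[float]] = {}
        for ts, _g in subs:
            res = _global_aucs(compute_lofc(ts), n_null, int(rng.integers(2**31)))
            for m, v in res.items():
                aucs.setdefault(m, []).append(v)
        for m, vals in aucs.items():
            gc = adjusted_group_test(np.array(vals), groups, metric_name=m)
            rejections += gc.p_value < 0.05
            total += 1
    return rejections / total


def planted_effect_recovery(
    n_cohorts: int = 50,
    delta: float = -0.25,
    n_perm: int = 500,
    primary_alpha: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Recovery of a planted 6-edge within-module effect.

    Each cohort: 30+30 subjects, 20 regions in 5 modules of 4, T = 200,
    with ``delta`` added to the within-SMN correlations of group B (the
    SMN block of 4 regions spans exactly 6 edges). Reports the fraction of
    cohorts in which NBS finds a significant component containing at least
    4 of the 6 planted edges (corrected p < 0.05), and the fraction in
    which the intra-SMN FC reduction is detected at p < 0.05.
    """
    rng = np.random.default_rng(seed)
    part = even_partition(20)
    partition = ModulePartition(part)
    nbs_hits, intra_hits = 0, 0
    groups = np.array(["A"] * 30 + ["B"] * 30)
    for _ in range(n_cohorts):
        design = CohortDesign(
            n_group_a=30, n_group_b=30, n_regions=20, n_timepoints=200,
            partition=part, effects=[EffectSpec("SMN", delta)],
            seed=int(rng.integers(2**31)),
        )
        subs, truth = generate_cohort(design)
        mats = [compute_lofc(ts) for ts, _g in subs]
        a, b = mats[:30], mats[30:]
        res = nbs(a, b, primary_alpha=primary_alpha, n_perm=n_perm,
                  seed=int(rng.integers(2**31)))
        idx = {l: i for i, l in enumerate(truth.region_labels)}
        planted = {tuple(sorted((idx[x], idx[y]))) for x, y in truth.affected_edges}
        for comp in res.significant(0.05):
            if len(planted & {tuple(sorted(e)) for e in comp["edges"]}) >= 4:
                nbs_hits += 1
                break
        intra = np.array([intra_modular_fc(cm, partition)["SMN"] for cm in mats])
        gc = adjusted_group_test(intra, groups)
        intra_hits += (gc.p_value < 0.05) and (gc.direction == int(np.sign(delta)))
    return {"nbs_recovery": nbs_hits / n_cohorts, "intra_detection": intra_hits / n_cohorts}


def classification_sanity(n_shuffles: int = 50, seed: int = 0) -> dict[str, float]:
    """Separable cohort -> LOOCV AUC; shuffled labels -> mean null AUC.

    The separable cohort plants a +0.40 within-module correlation increase
    (an effect several subject-level standard errors wide on each of its 6
    edges), which a linear SVM must separate perfectly. The null cohort
    has no effect; its labels are re-shuffled ``n_shuffles`` times.
    """
    rng = np.random.default_rng(seed)
    part = even_partition(20)
    sep_design = CohortDesign(
        n_group_a=15, n_group_b=15, n_regions=20, n_timepoints=200,
        partition=part, effects=[EffectSpec("SMN", +0.40)],
        seed=int(rng.integers(2**31)),
    )
    subs, _ = generate_cohort(sep_design)
    feats = build_features([compute_lofc(ts) for ts, _g in subs],
                           [g for _ts, g in subs])
    sep_auc = svm_loocv(feats, positive_label="B").auc

    null_design = CohortDesign(
        n_group_a=15, n_group_b=15, n_regions=20, n_timepoints=200,
        partition=part, seed=int(rng.integers(2**31)),
    )
    subs0, _ = generate_cohort(null_design)
    x = build_features([compute_lofc(ts) for ts, _g in subs0],
                       [g for _ts, g in subs0])
    null_aucs = []
    for _ in range(n_shuffles):
        shuffled = rng.permutation(x.groups)
        fm = FeatureMatrix(x.x, x.feature_names, shuffled)
        null_aucs.append(svm_loocv(fm, positive_label="B").auc)
    return {"separable_auc": float(sep_auc), "null_auc_mean": float(np.mean(null_aucs))}
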