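"""End-to-end pipeline orchestration.

Given a cohort manifest (subject id, group, covariates, time-series file),
the pipeline runs, in order: LOFC and HOFC construction -> binarization
over the sparsity grid -> global metrics with degree-preserving
small-world normalization and nodal metrics -> per-subject AUC summaries
-> modular FC -> covariate-adjusted group tests (FDR for nodal metrics)
-> NBS on the weighted matrices -> brain-behavior correlations ->
LASSO+SVM leave-one-out classification, for both network orders.

All tables are plain delimited text, every table carries the resolved
config hash in a leading comment line, and a frozen copy of the resolved
config is written next to the results. A single global seed fans out to
per-stage seeds by stable hashing of (seed, stage, key), so each stage is
reproducible in isolation and a rerun with the same seed is byte
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .classify import build_features, svm_loocv
from .fc import ConnectivityMatrix, SparsityGrid, binarize_at_sparsity, compute_hofc, compute_lofc
from .modular import ModulePartition, modular_fc_table
from .stats import adjusted_group_test, fdr_bh, nbs, partial_spearman
from .topology import (
    SparsityCurve,
    auc_over_sparsity,
    global_graph_metrics,
    nodal_graph_metrics,
    normalize_small_world,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: str
    out_dir: str
    partition_file: str | None = None
    sparsity_min: float = 0.10
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    n_null: int = 100
    n_swaps_factor: float = 10.0
    nbs_primary_alpha: float = 0.05
    nbs_n_perm: int = 10_000
    nbs_statistic: str = "extent"
    lasso_lam: float = 0.05
    svm_c: float = 1.0
    svm_kernel: str = "linear"
    covariate_columns: list[str] = field(default_factory=list)
    clinical_columns: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if self.partition_file is not None and not Path(self.partition_file).exists():
            raise FileNotFoundError(f"partition file not found: {self.partition_file}")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity step must be positive")

    def grid(self) -> SparsityGrid:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        levels = np.round(self.sparsity_min + self.sparsity_step * np.arange(n), 10)
        return SparsityGrid(levels=levels)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def stage_seed(seed: int, stage: str, key: str = "") -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the results directory.

    Any stage failure raises with the stage name (and subject id where
    applicable); tables written before the failure are retained.
    """
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    with open(out / "config_frozen.yaml", "w") as fh:
        yaml.safe_dump({**asdict(config), "config_hash": cfg_hash}, fh, sort_keys=True)

    manifest = hio.read_manifest(config.manifest)
    base = Path(config.manifest).parent
    groups = manifest["group"].to_numpy()
    subject_ids = manifest["subject_id"].astype(str).tolist()
    covariates = (
        manifest[config.covariate_columns].astype(float)
        if config.covariate_columns
        else None
    )
    grid = config.grid()
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = time.time()
        log.info("stage %s", name)

    # ---- connectivity construction --------------------------------------
    _stage("fc_construction")
    matrices: dict[str, list[ConnectivityMatrix]] = {"low": [], "high": []}
    for sid, fname in zip(subject_ids, manifest["timeseries_file"]):
        try:
            ts = hio.read_timeseries_table(base / fname, subject_id=sid)
            lofc = compute_lofc(ts)
            hofc = compute_hofc(lofc)
        except Exception as exc:
            raise RuntimeError(f"stage fc_construction failed for subject {sid}: {exc}") from exc
        matrices["low"].append(lofc)
        matrices["high"].append(hofc)
    mat_dir = out / "connectivity"
    mat_dir.mkdir(exist_ok=True)
    for order in ("low", "high"):
        for sid, cm in zip(subject_ids, matrices[order]):
            hio.write_connectivity_matrix(cm, mat_dir / f"{sid}_{order}.tsv")

    # ---- topology over the sparsity grid --------------------------------
    _stage("graph_topology")
    region_labels = matrices["low"][0].region_labels
    n_regions = len(region_labels)
    global_rows, nodal_auc = [], {}
    auc_rows = []
    for order in ("low", "high"):
        nodal_curves = {m: np.zeros((len(subject_ids), len(grid), n_regions))
                        for m in ("degree", "efficiency", "betweenness")}
        for si, (sid, cm) in enumerate(zip(subject_ids, matrices[order])):
            try:
                per_metric = {m: [] for m in
                              ("gamma", "lambda", "sigma", "Lp", "Cp", "Eglob", "Eloc")}
                for li, s in enumerate(grid):
                    g = binarize_at_sparsity(cm, float(s))
                    raw = global_graph_metrics(g)
                    sw = normalize_small_world(
                        g,
                        n_null=config.n_null,
                        n_swaps=max(1, int(config.n_swaps_factor * g.n_edges)),
                        seed=stage_seed(config.seed, "null", f"{order}:{sid}:{s}"),
                    )
                    vals = dict(gamma=sw.gamma, sigma=sw.sigma, Lp=raw.Lp, Cp=raw.Cp,
                                Eglob=raw.Eglob, Eloc=raw.Eloc)
                    vals["lambda"] = sw.lam
                    for m, v in vals.items():
                        per_metric[m].append(v)
                        global_rows.append(
                            dict(order=order, subject_id=sid, sparsity=float(s),
                                 metric=m, value=v)
                        )
                    nm = nodal_graph_metrics(g)
                    nodal_curves["degree"][si, li] = nm.degree
                    nodal_curves["efficiency"][si, li] = nm.efficiency
                    nodal_curves["betweenness"][si, li] = nm.betweenness
                for m, vals in per_metric.items():
                    auc = auc_over_sparsity(SparsityCurve(grid, np.array(vals), m))
                    auc_rows.append(dict(order=order, subject_id=sid, metric=m, auc=auc))
            except Exception as exc:
                raise RuntimeError(f"stage graph_topology failed for subject {sid}: {exc}") from exc
        for m, cube in nodal_curves.items():
            nodal_auc[(order, m)] = np.trapezoid(cube, grid.levels, axis=1)
    _write_table(pd.DataFrame(global_rows), out / "global_metrics_by_sparsity.tsv", cfg_hash)
    auc_df = pd.DataFrame(auc_rows)
    _write_table(auc_df, out / "global_metrics_auc.tsv", cfg_hash)

    # ---- modular FC ------------------------------------------------------
    _stage("modular_fc")
    partition = (
        hio.read_partition(config.partition_file)
        if config.partition_file
        else ModulePartition(hio.load_default_partition())
    )
    mod_rows = []
    for order in ("low", "high"):
        for sid, cm in zip(subject_ids, matrices[order]):
            row = dict(order=order, subject_id=sid)
            row.update(modular_fc_table(cm, partition))
            mod_rows.append(row)
    mod_df = pd.DataFrame(mod_rows)
    _write_table(mod_df, out / "modular_fc.tsv", cfg_hash)

    # ---- group inference -------------------------------------------------
    _stage("group_inference")
    comp_rows = []
    for order in ("low", "high"):
        sub = auc_df[auc_df.order == order]
        for m in sub.metric.unique():
            vals = sub[sub.metric == m].set_index("subject_id").loc[subject_ids, "auc"].to_numpy()
            gc = adjusted_group_test(vals, groups, covariates, metric_name=m)
            comp_rows.append(dict(order=order, family="global_auc", metric=m,
                                  t=gc.t_stat, p=gc.p_value, direction=gc.direction))
        mrows = mod_df[mod_df.order == order].set_index("subject_id").loc[subject_ids]
        for colname in mrows.columns:
            if colname == "order":
                continue
            gc = adjusted_group_test(
                mrows[colname].to_numpy(dtype=float), groups, covariates, metric_name=colname
            )
            comp_rows.append(dict(order=order, family="modular_fc", metric=colname,
                                  t=gc.t_stat, p=gc.p_value, direction=gc.direction))
        for m in ("degree", "efficiency", "betweenness"):
            mat = nodal_auc[(order, m)]
            ps, ts, dirs = [], [], []
            for node in range(n_regions):
                gc = adjusted_group_test(mat[:, node], groups, covariates)
                ps.append(gc.p_value)
                ts.append(gc.t_stat)
                dirs.append(gc.direction)
            adj = fdr_bh(ps)
            for node in range(n_regions):
                comp_rows.append(dict(order=order, family=f"nodal_{m}",
                                      metric=region_labels[node], t=ts[node],
                                      p=ps[node], p_fdr=adj[node], direction=dirs[node]))
    comp_df = pd.DataFrame(comp_rows)
    _write_table(comp_df, out / "group_comparisons.tsv", cfg_hash)

    # ---- NBS -------------------------------------------------------------
    _stage("nbs")
    group_labels = pd.unique(groups)
    nbs_rows = []
    for order in ("low", "high"):
        mats_a = [cm for cm, g in zip(matrices[order], groups) if g == group_labels[0]]
        mats_b = [cm for cm, g in zip(matrices[order], groups) if g == group_labels[1]]
        res = nbs(
            mats_a, mats_b, covariates,
            primary_alpha=config.nbs_primary_alpha,
            n_perm=config.nbs_n_perm,
            seed=stage_seed(config.seed, "nbs", order),
            statistic=config.nbs_statistic,
        )
        for ci, comp in enumerate(res.components):
            for i, j in comp["edges"]:
                nbs_rows.append(dict(
                    order=order, component=ci, size=comp["size"],
                    corrected_p=comp["corrected_p"],
                    region_i=region_labels[i], region_j=region_labels[j],
                    t=res.t_values[_edge_index(i, j, n_regions)],
                ))
    _write_table(pd.DataFrame(nbs_rows), out / "nbs_edges.tsv", cfg_hash)

    # ---- brain-behavior correlations ------------------------------------
    _stage("correlations")
    corr_rows = []
    if config.clinical_columns:
        mask_b = groups == group_labels[1]
        for order in ("low", "high"):
            sub = auc_df[auc_df.order == order]
            for m in sub.metric.unique():
                vals = sub[sub.metric == m].set_index("subject_id").loc[subject_ids, "auc"].to_numpy()
                for col in config.clinical_columns:
                    score = manifest.loc[mask_b, col].to_numpy(dtype=float)
                    cov_b = covariates[mask_b] if covariates is not None else None
                    cr = partial_spearman(vals[mask_b], score, cov_b)
                    corr_rows.append(dict(order=order, metric=m, score=col,
                                          rho=cr.rho, p=cr.p_value, n=cr.n))
    _write_table(pd.DataFrame(corr_rows), out / "correlations.tsv", cfg_hash)

    # ---- classification --------------------------------------------------
    _stage("classification")
    clf_rows = []
    for order in ("low", "high"):
        feats = build_features(matrices[order], groups)
        res = svm_loocv(feats, lam=config.lasso_lam, svm_c=config.svm_c,
                        kernel=config.svm_kernel, positive_label=group_labels[1])
        clf_rows.append(dict(order=order, auc=res.auc, accuracy=res.accuracy,
                             sensitivity=res.sensitivity, specificity=res.specificity))
        pred_df = pd.DataFrame(dict(subject_id=subject_ids, group=groups,
                                    score=res.scores, prediction=res.predictions))
        _write_table(pred_df, out / f"classification_predictions_{order}.tsv", cfg_hash)
    _write_table(pd.DataFrame(clf_rows), out / "classification_summary.tsv", cfg_hash)

    # ---- log -------------------------------------------------------------
    now = time.time()
    stages = list(timings)
    with open(out / "pipeline_log.txt", "w") as fh:
        fh.write(f"config_hash={cfg_hash}\n")
        for name, start in timings.items():
            nxt = stages.index(name) + 1
            end = timings[stages[nxt]] if nxt < len(stages) else now
            fh.write(f"{name}\t{end - start:.2f}s\n")
        fh.write(f"total\t{now - t0:.2f}s\n")
    return out


def _edge_index(i: int, j: int, n: int) -> int:
    """Index of edge (i < j) in the row-major strict upper triangle."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)
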