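"""Plain-text readers and writers.

Everything the pipeline touches is delimited text: per-subject time-series
tables (rows = time points, columns = regions, header = region labels),
connectivity matrices with a label header row and column, a two-column
partition file (region, module), an atlas label list (one region per
line), a cohort manifest CSV and a JSON ground-truth sidecar for synthetic
cohorts. Delimiters are auto-detected among comma and tab.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortDesign, EffectSpec, GroundTruth
from .fc import ConnectivityMatrix, RoiTimeSeries
from .modular import ModulePartition

__all__ = [
    "read_timeseries_table",
    "write_timeseries_table",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "read_partition",
    "read_labels",
    "load_default_labels",
    "load_default_partition",
    "write_cohort",
    "read_manifest",
]


def _detect_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_timeseries_table(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    """Read one subject's T x N time-series table.

    Raises with the offending line (and column) for ragged rows,
    non-numeric cells and duplicate region labels.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header line and at least one data row")
    delim = _detect_delimiter(lines[0])
    labels = [c.strip() for c in lines[0].split(delim)]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate region labels {dupes}")
    n = len(labels)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delim)
        if len(cells) != n:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} cells, expected {n} (ragged row)"
            )
        row = []
        for col, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at line {lineno}, column {col}: {cell!r}"
                ) from None
        rows.append(row)
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=np.array(rows),
        region_labels=labels,
    )


def write_timeseries_table(ts: RoiTimeSeries, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(ts.region_labels) + "\n")
        for row in ts.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def write_connectivity_matrix(cm: ConnectivityMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(cm.values, index=cm.region_labels, columns=cm.region_labels)
    df.to_csv(path, sep=delimiter, float_format="%.10g")


def read_connectivity_matrix(path: str | Path, order: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        order=order,
        region_labels=[str(c) for c in df.columns],
    )


def read_labels(path: str | Path) -> list[str]:
    """Atlas label file: one region name per line."""
    with open(path) as fh:
        labels = [ln.strip() for ln in fh if ln.strip()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate labels")
    return labels


def read_partition(path: str | Path) -> ModulePartition:
    """Two-column delimited file: region label, module label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            delim = _detect_delimiter(ln)
            cells = [c.strip() for c in ln.split(delim)]
            if len(cells) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
            region, module = cells
            if region in mapping:
                raise ValueError(f"{path}: line {lineno}: region {region!r} assigned twice")
            mapping[region] = module
    return ModulePartition(mapping)


def load_default_labels() -> list[str]:
    """The 90-region AAL atlas label list shipped with the package."""
    ref = resources.files("hofcnet.data") / "aal90_labels.txt"
    return [ln.strip() for ln in ref.read_text().splitlines() if ln.strip()]


def load_default_partition() -> dict[str, str]:
    """Default AAL-90 -> 5-module assignment.

    This is a constructed (synthetic) assignment of the 90 AAL regions to
    the SMN/DMN/FPN/VN/SN systems based on their anatomical membership; it
    stands in for a published partition and can be overridden by any
    two-column partition file via :func:`read_partition`.
    """
    ref = resources.files("hofcnet.data") / "aal90_partition_synthetic.tsv"
    mapping: dict[str, str] = {}
    for ln in ref.read_text().splitlines():
        if ln.strip():
            region, module = ln.split("\t")
            mapping[region] = module
    return mapping


def write_cohort(
    subjects: list[tuple[RoiTimeSeries, str]],
    truth: GroundTruth,
    out_dir: str | Path,
    covariates: pd.DataFrame | None = None,
) -> Path:
    """Write a synthetic cohort: one table per subject + manifest + ground truth.

    Returns the manifest path. The manifest has columns subject_id, group,
    timeseries_file and any covariate columns supplied (aligned by row
    order with ``subjects``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (ts, group) in enumerate(subjects):
        fname = f"{ts.subject_id}.tsv"
        write_timeseries_table(ts, out_dir / fname)
        row = {"subject_id": ts.subject_id, "group": group, "timeseries_file": fname}
        if covariates is not None:
            row.update(covariates.iloc[k].to_dict())
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    design = truth.design
    sidecar = {
        "design": {
            "n_group_a": design.n_group_a,
            "n_group_b": design.n_group_b,
            "n_regions": design.n_regions,
            "n_timepoints": design.n_timepoints,
            "base_within_cov": design.base_within_cov,
            "base_between_cov": design.base_between_cov,
            "noise_sd": design.noise_sd,
            "ar_coef": design.ar_coef,
            "seed": design.seed,
            "partition": design.partition,
            "effects": [
                {"target": list(e.target) if isinstance(e.target, tuple) else e.target,
                 "delta": e.delta, "applies_to": e.applies_to}
                for e in design.effects
            ],
        },
        "affected_edges": [list(e) for e in truth.affected_edges],
        "covariance_a": truth.covariance_a.tolist(),
        "covariance_b": truth.covariance_b.tolist(),
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "timeseries_file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    if df["group"].nunique() != 2:
        raise ValueError(f"{path}: expected exactly 2 group labels")
    base = Path(path).parent
    for f in df["timeseries_file"]:
        if not (base / f).exists():
            raise FileNotFoundError(f"{path}: time-series file not found: {f}")
    return df


def read_design(path: str | Path) -> CohortDesign:
    """Cohort design from a JSON file (same schema as the ground-truth sidecar)."""
    with open(path) as fh:
        raw = json.load(fh)
    d = raw.get("design", raw)
    effects = [
        EffectSpec(
            target=tuple(e["target"]) if isinstance(e["target"], list) else e["target"],
            delta=e["delta"],
            applies_to=e.get("applies_to", "within"),
        )
        for e in d.get("effects", [])
    ]
    return CohortDesign(
        n_group_a=d["n_group_a"],
        n_group_b=d["n_group_b"],
        n_regions=d["n_regions"],
        n_timepoints=d["n_timepoints"],
        partition=d["partition"],
        base_within_cov=d.get("base_within_cov", 0.35),
        base_between_cov=d.get("base_between_cov", 0.10),
        effects=effects,
        noise_sd=d.get("noise_sd", 0.5),
        ar_coef=d.get("ar_coef", 0.0),
        seed=d.get("seed", 0),
    )
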