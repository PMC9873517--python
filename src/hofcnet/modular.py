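"""Intra- and inter-modular functional connectivity.

Modular FC summarizes the weighted (unthresholded) connectivity matrix over
an a-priori partition of regions into modules — by default the five
large-scale systems SMN (sensorimotor), DMN (default mode), FPN
(frontoparietal), VN (visual) and SN (subcortical). Intra-modular FC of a
module is the mean weight over all its within-module region pairs;
inter-modular FC of a module pair is the mean weight over all cross-module
region pairs. Negative weights are retained (the removal of negative
weights applies only to binarization for graph metrics).

A binary variant averaged over a sparsity grid is available behind
``binarized_grid`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .fc import ConnectivityMatrix, SparsityGrid, binarize_at_sparsity

__all__ = ["ModulePartition", "intra_modular_fc", "inter_modular_fc", "modular_fc_table"]

DEFAULT_MODULES = ("SMN", "DMN", "FPN", "VN", "SN")


@dataclass
class ModulePartition:
    """Mapping region label -> module label; every region exactly once, >= 2 per module."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for m in self.mapping.values():
            counts[m] = counts.get(m, 0) + 1
        small = [m for m, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"module(s) with fewer than 2 regions: {small}")
        self._counts = counts

    @property
    def module_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.mapping.values():
            seen.setdefault(m)
        return list(seen)

    def indices(self, region_labels: list[str]) -> dict[str, np.ndarray]:
        missing = [r for r in region_labels if r not in self.mapping]
        if missing:
            raise ValueError(f"regions missing from partition: {missing[:5]}")
        modules = np.array([self.mapping[r] for r in region_labels])
        return {m: np.flatnonzero(modules == m) for m in self.module_labels}


def _module_indices(cm: ConnectivityMatrix, part: ModulePartition) -> dict[str, np.ndarray]:
    idx = part.indices(cm.region_labels)
    small = [m for m, ix in idx.items() if ix.size < 2]
    if small:
        raise ValueError(f"module(s) with fewer than 2 regions in this matrix: {small}")
    return idx


def intra_modular_fc(cm: ConnectivityMatrix, part: ModulePartition) -> dict[str, float]:
    """Mean weighted connectivity over within-module region pairs, per module."""
    idx = _module_indices(cm, part)
    out = {}
    for m, ix in idx.items():
        block = cm.values[np.ix_(ix, ix)]
        iu = np.triu_indices(ix.size, k=1)
        out[m] = float(block[iu].mean())
    return out


def inter_modular_fc(cm: ConnectivityMatrix, part: ModulePartition) -> dict[tuple[str, str], float]:
    """Mean weighted connectivity over cross-module region pairs, per unordered module pair."""
    idx = _module_indices(cm, part)
    out = {}
    for m1, m2 in combinations(idx.keys(), 2):
        block = cm.values[np.ix_(idx[m1], idx[m2])]
        out[(m1, m2)] = float(block.mean())
    return out


def modular_fc_table(
    cm: ConnectivityMatrix,
    part: ModulePartition,
    binarized_grid: SparsityGrid | None = None,
) -> dict[str, float]:
    """Flat {name: value} of all intra and inter modular FC for one subject.

    With ``binarized_grid`` the matrix is first binarized at each grid level
    and the modular means of the 0/1 adjacency are averaged over the grid
    (density-style variant); default is the weighted matrix.
    """
    if binarized_grid is not None:
        mats = [
            ConnectivityMatrix(
                binarize_at_sparsity(cm, float(s)).adjacency.astype(float),
                cm.order,
                cm.region_labels,
            )
            for s in binarized_grid
        ]
    else:
        mats = [cm]
    acc: dict[str, float] = {}
    for mat in mats:
        for m, v in intra_modular_fc(mat, part).items():
            acc[f"intra_{m}"] = acc.get(f"intra_{m}", 0.0) + v
        for (m1, m2), v in inter_modular_fc(mat, part).items():
            acc[f"inter_{m1}_{m2}"] = acc.get(f"inter_{m1}_{m2}", 0.0) + v
    return {k: v / len(mats) for k, v in acc.items()}
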