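"""Synthetic two-group cohorts of modular multivariate time series.

The generator emulates a resting-state ROI-level dataset: two groups of
subjects, each subject a T x N multivariate normal time series whose
population correlation matrix has a block (module) structure — higher
correlation within a module than between modules. Group differences are
injected as additive shifts ("effects") on the correlation of chosen
within-module blocks or module pairs in group B only, giving every
downstream statistic a known ground truth.

Observation noise is added independently per sample, and an optional AR(1)
coefficient induces temporal autocorrelation while preserving the
stationary spatial covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fc import RoiTimeSeries

__all__ = ["EffectSpec", "CohortDesign", "GroundTruth", "population_covariance",
           "generate_cohort", "default_design"]

GROUP_A = "A"
GROUP_B = "B"


@dataclass(frozen=True)
class EffectSpec:
    """A group-B-only shift of one block of the population correlation.

    target : module label (applies_to="within") or ordered pair of module
        labels (applies_to="between").
    delta : signed shift added to every correlation in the target block.
    """

    target: str | tuple[str, str]
    delta: float
    applies_to: str = "within"

    def __post_init__(self) -> None:
        if self.applies_to not in ("within", "between"):
            raise ValueError("applies_to must be 'within' or 'between'")
        if self.applies_to == "within" and not isinstance(self.target, str):
            raise ValueError("within-module effect target must be a module label")
        if self.applies_to == "between" and (
            not isinstance(self.target, tuple) or len(self.target) != 2
        ):
            raise ValueError("between-module effect target must be a (module, module) pair")


@dataclass
class CohortDesign:
    """Ground-truth specification of a synthetic cohort.

    partition maps each region label to one of the module labels; the
    region order of the generated data is the insertion order of this
    mapping. base_within_cov / base_between_cov are the within-block and
    between-block correlations of group A (and of group B before effects).
    """

    n_group_a: int
    n_group_b: int
    n_regions: int
    n_timepoints: int
    partition: dict[str, str]
    base_within_cov: float = 0.35
    base_between_cov: float = 0.10
    effects: list[EffectSpec] = field(default_factory=list)
    noise_sd: float = 0.5
    ar_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if len(self.partition) != self.n_regions:
            raise ValueError(
                f"partition has {len(self.partition)} regions, design says {self.n_regions}"
            )
        if not (0 <= self.base_between_cov < self.base_within_cov < 1):
            raise ValueError(
                "require 0 <= base_between_cov < base_within_cov < 1"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must be in (-1, 1)")
        # fail loudly (naming the block) rather than sampling a non-PD matrix
        for group in (GROUP_A, GROUP_B):
            population_covariance(self, group)

    @property
    def region_labels(self) -> list[str]:
        return list(self.partition.keys())

    @property
    def module_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.partition.values():
            seen.setdefault(m)
        return list(seen)


@dataclass
class GroundTruth:
    """What the generator actually used: population matrices and the edges they differ on."""

    covariance_a: np.ndarray
    covariance_b: np.ndarray
    affected_edges: list[tuple[str, str]]
    region_labels: list[str]
    design: CohortDesign


def _block_masks(design: CohortDesign) -> dict[str, np.ndarray]:
    modules = np.array([design.partition[r] for r in design.region_labels])
    return {m: modules == m for m in design.module_labels}


def population_covariance(design: CohortDesign, group: str) -> np.ndarray:
    """Exact population correlation matrix used for sampling one group.

    Raises if the implied matrix is not symmetric positive definite,
    naming the offending effect block, or if any shifted correlation
    leaves (-1, 1).
    """
    if group not in (GROUP_A, GROUP_B):
        raise ValueError(f"unknown group label {group!r}; use {GROUP_A!r} or {GROUP_B!r}")
    masks = _block_masks(design)
    n = design.n_regions
    sigma = np.full((n, n), design.base_between_cov)
    for mask in masks.values():
        blk = np.outer(mask, mask)
        sigma[blk] = design.base_within_cov
    np.fill_diagonal(sigma, 1.0)
    if group == GROUP_B:
        for eff in design.effects:
            if eff.delta == 0:
                continue
            if eff.applies_to == "within":
                if eff.target not in masks:
                    raise ValueError(f"effect targets unknown module {eff.target!r}")
                mask = masks[eff.target]
                blk = np.outer(mask, mask) & ~np.eye(n, dtype=bool)
            else:
                m1, m2 = eff.target
                if m1 not in masks or m2 not in masks:
                    raise ValueError(f"effect targets unknown module pair {eff.target!r}")
                blk = np.outer(masks[m1], masks[m2]) | np.outer(masks[m2], masks[m1])
            sigma[blk] += eff.delta
            vals = sigma[blk]
            if vals.size and (vals.min() <= -1 or vals.max() >= 1):
                raise ValueError(
                    f"effect on {eff.target!r} pushes correlations outside (-1, 1)"
                )
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin <= 0:
        raise ValueError(
            f"implied covariance for group {group} is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e}); offending effects: "
            f"{[e.target for e in design.effects] if group == GROUP_B else 'base design'}"
        )
    return sigma


def _sample_subject(rng: np.random.Generator, chol: np.ndarray, t: int,
                    noise_sd: float, ar: float) -> np.ndarray:
    n = chol.shape[0]
    innov = rng.standard_normal((t, n)) @ chol.T
    if ar != 0.0:
        x = np.empty_like(innov)
        scale = np.sqrt(1.0 - ar * ar)
        x[0] = innov[0]
        for k in range(1, t):
            x[k] = ar * x[k - 1] + scale * innov[k]
    else:
        x = innov
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=(t, n))
    return x


def generate_cohort(design: CohortDesign) -> tuple[list[tuple[RoiTimeSeries, str]], GroundTruth]:
    """Draw the full cohort.

    Returns ``(subjects, truth)`` where subjects is a list of
    ``(RoiTimeSeries, group_label)`` with group A first, and truth records
    the two population correlation matrices plus the edges on which they
    differ. The same seed reproduces the cohort bit for bit.
    """
    sigma_a = population_covariance(design, GROUP_A)
    sigma_b = population_covariance(design, GROUP_B)
    if design.n_timepoints < design.n_regions:
        warnings.warn(
            f"n_timepoints ({design.n_timepoints}) < n_regions ({design.n_regions}): "
            "sample correlation matrices will be rank-deficient",
            stacklevel=2,
        )
    labels = design.region_labels
    diff = np.argwhere(np.triu(~np.isclose(sigma_a, sigma_b), k=1))
    affected = [(labels[i], labels[j]) for i, j in diff]
    rng = np.random.default_rng(design.seed)
    chol_a = np.linalg.cholesky(sigma_a)
    chol_b = np.linalg.cholesky(sigma_b)
    subjects: list[tuple[RoiTimeSeries, str]] = []
    for k in range(design.n_group_a):
        data = _sample_subject(rng, chol_a, design.n_timepoints, design.noise_sd, design.ar_coef)
        subjects.append(
            (RoiTimeSeries(f"subA{k + 1:03d}", data, list(labels)), GROUP_A)
        )
    for k in range(design.n_group_b):
        data = _sample_subject(rng, chol_b, design.n_timepoints, design.noise_sd, design.ar_coef)
        subjects.append(
            (RoiTimeSeries(f"subB{k + 1:03d}", data, list(labels)), GROUP_B)
        )
    truth = GroundTruth(sigma_a, sigma_b, affected, list(labels), design)
    return subjects, truth


def default_design(effects: list[EffectSpec] | None = None, seed: int = 0) -> CohortDesign:
    """Design mirroring the study cohort: 60 + 51 subjects, 90 regions, 230 time points."""
    from .io import load_default_partition

    partition = load_default_partition()
    return CohortDesign(
        n_group_a=60,
        n_group_b=51,
        n_regions=90,
        n_timepoints=230,
        partition=partition,
        effects=effects or [],
        seed=seed,
    )
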