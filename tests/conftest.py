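import numpy as np
import pytest

from hofcnet import CohortDesign, EffectSpec


def five_module_partition(n_regions: int = 20) -> dict[str, str]:
    """n_regions regions split evenly over SMN/DMN/FPN/VN/SN."""
    modules = ["SMN", "DMN", "FPN", "VN", "SN"]
    per = n_regions // len(modules)
    assert per * len(modules) == n_regions
    return {f"r{i:02d}": modules[i // per] for i in range(n_regions)}


@pytest.fixture
def partition20() -> dict[str, str]:
    return five_module_partition(20)


@pytest.fixture
def null_design(partition20) -> CohortDesign:
    """Zero-effect two-group design (identical populations)."""
    return CohortDesign(
        n_group_a=30, n_group_b=30, n_regions=20, n_timepoints=100,
        partition=partition20, seed=7,
    )


@pytest.fixture
def effect_design(partition20) -> CohortDesign:
    """Design with a within-SMN correlation reduction in group B."""
    return CohortDesign(
        n_group_a=30, n_group_b=30, n_regions=20, n_timepoints=200,
        partition=partition20, effects=[EffectSpec("SMN", -0.25)], seed=11,
    )


def random_binary_graph(rng: np.random.Generator, n: int, p: float):
    from hofcnet import BinaryGraph

    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, k=1)
    a = a + a.T
    return BinaryGraph(adjacency=a, sparsity=float(a.sum() / (n * (n - 1))))
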