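import numpy as np
import pandas as pd
import pytest

from cachexnet.normalize import CountMatrix
from cachexnet.simulate import SimulationConfig, simulate_paired_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_genes=600, n_mirnas=80)


@pytest.fixture(scope="session")
def small_simulation(small_config):
    """One paired simulation shared by read-only tests."""
    return simulate_paired_counts(small_config)


@pytest.fixture(scope="session")
def subgroup_simulation():
    cfg = SimulationConfig(seed=11, n_genes=600, n_mirnas=80)
    return simulate_paired_counts(cfg, subgroup_mode=True)


@pytest.fixture
def toy_count_matrix() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "C1": [100, 10, 1000, 50],
            "C2": [120, 12, 900, 55],
            "L1": [300, 30, 2800, 40],
            "L2": [280, 28, 3100, 60],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    groups = pd.Series(
        ["control", "control", "case", "case"], index=counts.columns
    )
    return CountMatrix(counts, groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
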