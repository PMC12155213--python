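import numpy as np
import pytest

from rrsburn.grid import WavenumberGrid
from rrsburn.synthetic import SimulationConfig, default_libraries


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid()


@pytest.fixture(scope="session")
def libs(grid):
    return default_libraries(grid)


@pytest.fixture(scope="session")
def lib_list(libs):
    return list(libs.values())


@pytest.fixture
def noiseless_cfg(grid):
    return SimulationConfig(grid=grid, noise_sd=0.0, spike_prob=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
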