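import numpy as np
import pytest

from sccompreg.simulate import Scenario, SimulationParams, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_combined_dataset():
    """A small combined-scenario dataset shared across tests (read-only)."""
    params = SimulationParams(
        n_tf=12, n_tg=80, n_re=60, n_cells=120,
        scenario=Scenario.combined, seed=11,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """One benchmark-size combined dataset shared by slower tests."""
    return simulate_dataset(SimulationParams(scenario=Scenario.combined, seed=1))
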