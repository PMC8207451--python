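import numpy as np
import pytest

from pairbond_cjs import HistoryCounts, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def null_config():
    """Reference study conditions with independent fates."""
    return SimulationConfig(gamma=0.0, rho=0.0, n_replicates=5, seed=42)


@pytest.fixture
def small_null_counts():
    """History counts from one small independent-fates dataset."""
    data = simulate_dataset(SimulationConfig(n=120, seed=7))
    return HistoryCounts.from_dataset(data)
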