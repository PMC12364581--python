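import numpy as np
import pytest

from togglesim.boolean_sim import SimulationConfig


@pytest.fixture
def fast_config():
    """Small Monte-Carlo budget for unit tests."""
    return SimulationConfig(n_initial_conditions=3000, n_replicates=1, seed=11)


@pytest.fixture
def replicate_config():
    """Three-replicate budget, large enough for ±0.03 frequency checks."""
    return SimulationConfig(n_initial_conditions=5000, n_replicates=3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
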