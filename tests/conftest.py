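import numpy as np
import pytest

from orpan.simulate import LorenzConfig, simulate_coupled_lorenz


@pytest.fixture(scope="session")
def lorenz_uncoupled():
    """One uncoupled (g=0) realization of the benchmark protocol."""
    return simulate_coupled_lorenz(LorenzConfig(g=0.0, seed=7))


@pytest.fixture(scope="session")
def lorenz_coupled():
    """One coupled (g=5) realization of the benchmark protocol."""
    return simulate_coupled_lorenz(LorenzConfig(g=5.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
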