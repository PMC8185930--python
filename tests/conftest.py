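import numpy as np
import pytest

from waxspec import (
    SimulationConfig,
    SpectralSignature,
    baseline_leaf_spectrum,
    default_wax_profile,
    simulate_trial,
)
from waxspec.synthetic import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def leaf(grid):
    return baseline_leaf_spectrum(grid)


@pytest.fixture(scope="session")
def wax_profile():
    return default_wax_profile()


@pytest.fixture
def flat_sig(grid):
    """Constant 0.2 spectrum on the standard grid."""
    return SpectralSignature(grid, np.full(grid.size, 0.2))


@pytest.fixture(scope="session")
def small_trial():
    """One seeded simulated trial for cross-module tests."""
    return simulate_trial(SimulationConfig(seed=11))
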