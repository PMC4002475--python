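import numpy as np
import pytest

from puffsnr import FluctuationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def params():
    """Reference parameter set used across modules."""
    return FluctuationParams(gain=2.0, eps_bound=0.1, eps_free=0.01,
                             occupancy=0.25, mean_molecules=100.0)


@pytest.fixture
def basal_params():
    """Calibration-fixture truth: a basal-occupancy oocyte setting."""
    return FluctuationParams(gain=1.5, eps_bound=0.1, eps_free=0.005,
                             occupancy=0.1, mean_molecules=100.0)
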