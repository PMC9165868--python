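import numpy as np
import pytest

import hepatolip as hl
from hepatolip.scenarios import baseline_scenario
from hepatolip.simulate import find_steady_state


@pytest.fixture(scope="session")
def params():
    return hl.default_parameters()


@pytest.fixture(scope="session")
def qparams(params):
    return hl.nondimensionalize(params)


@pytest.fixture(scope="session")
def baseline(params):
    """Baseline scenario: fresh medium plus 1e12 molec./mL extracellular PCSK9."""
    return baseline_scenario(params, p_E0=1e12)


@pytest.fixture(scope="session")
def baseline_steady(baseline):
    """Reference fixed point of the baseline scenario (expensive; shared)."""
    return find_steady_state(baseline, residual_tol=1e-10)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220603)


def random_nonneg_state(rng, scale=1.0):
    return rng.uniform(0.0, scale, hl.N_STATES)
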