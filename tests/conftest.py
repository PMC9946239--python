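import numpy as np
import pytest

from paramecium.ephys import steady_state_init
from paramecium.params import preset


@pytest.fixture(scope="session")
def table3():
    """Median ciliated-cell parameters (fresh copy per use is not needed:
    tests must not mutate; mutating tests take .copy())."""
    return preset("table3_median")


@pytest.fixture(scope="session")
def balanced3(table3):
    """Resting state and balanced parameters of the default cell."""
    state, params = steady_state_init(table3)
    return state, params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
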