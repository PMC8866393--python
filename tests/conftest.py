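import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bgnet.params import default_params, gp_params, stn_params, tha_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture
def stn():
    return stn_params()


@pytest.fixture
def gp():
    return gp_params()


@pytest.fixture
def tha():
    return tha_params()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
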