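import numpy as np
import pytest

from fd2pool.fd2 import FD2Params


@pytest.fixture
def default_params() -> FD2Params:
    """Published dynamics constants, seven sites, full occupancy."""
    return FD2Params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190731)
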