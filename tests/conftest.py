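import numpy as np
import pytest

from cifns.geometry import (
    CochlearSpiralModel,
    default_facial_nerve,
    get_array,
    load_array_catalogue,
)
from cifns.synthetic_emg import ForwardModelParams


@pytest.fixture(scope="session")
def spiral():
    return CochlearSpiralModel()


@pytest.fixture(scope="session")
def facial_nerve(spiral):
    return default_facial_nerve(spiral)


@pytest.fixture(scope="session")
def catalogue():
    return load_array_catalogue()


@pytest.fixture(scope="session")
def flex28():
    return get_array("FLEX28")


@pytest.fixture
def quiet_params():
    """Forward model without measurement noise."""
    return ForwardModelParams(noise_sd_uv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
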