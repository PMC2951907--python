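import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcuflux import packaged_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def present_liver():
    return packaged_params("present/model1/liver")


@pytest.fixture
def present_heart():
    return packaged_params("present/model1/heart")


@pytest.fixture
def previous_liver():
    return packaged_params("previous/model1/case1/liver")
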