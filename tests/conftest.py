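import numpy as np
import pytest

from retinosnn.retina import build_retina_map
from retinosnn.synthetic import generate_v1_cloud


@pytest.fixture(scope="session")
def default_map():
    return build_retina_map(128)


@pytest.fixture(scope="session")
def small_cloud():
    """A 200-neuron V1-like cloud for fast reservoir tests."""
    return generate_v1_cloud(200, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
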