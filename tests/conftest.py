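import numpy as np
import pytest

from sonoseg import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(image_size=64, seed=11)


@pytest.fixture(scope="session")
def benign_sample(phantom_config):
    return make_phantom(phantom_config, "benign", 11)


@pytest.fixture(scope="session")
def malignant_sample(phantom_config):
    return make_phantom(phantom_config, "malignant", 12)


@pytest.fixture(scope="session")
def normal_sample(phantom_config):
    return make_phantom(phantom_config, "normal", 13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
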