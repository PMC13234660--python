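import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plasmavoc.synthetic import default_voc_config, generate_dataset, helium_config

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def voc_config():
    return default_voc_config()


@pytest.fixture(scope="session")
def voc_dataset(voc_config):
    """Default 24-category study condition: 5 train + 1 test per category,
    pixel noise sigma 2, fixed seed."""
    return generate_dataset(voc_config, seed=7)


@pytest.fixture(scope="session")
def helium_config_fixture():
    return helium_config()


@pytest.fixture(scope="session")
def helium_dataset(helium_config_fixture):
    return generate_dataset(helium_config_fixture, seed=8)
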