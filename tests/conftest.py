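import numpy as np
import pytest

from sepsisdyn.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def small_bundle(config):
    """One modest cohort shared across read-only tests."""
    return generate_cohort(config, 400, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
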