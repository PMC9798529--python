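import numpy as np
import pytest

from aromat import PriorConfig, build_default_card, compile_lookup
from aromat.posterior import init_prior


@pytest.fixture(scope="session")
def card():
    return build_default_card()


@pytest.fixture(scope="session")
def prior_config():
    return PriorConfig()


@pytest.fixture(scope="session")
def prior_grid(prior_config):
    return init_prior(prior_config)


@pytest.fixture(scope="session")
def lookup_table(card, prior_config):
    return compile_lookup(card, prior_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
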