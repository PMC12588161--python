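import numpy as np
import pandas as pd
import pytest

from lingtrait.psychometrics import ScaleDefinition
from lingtrait.synthetic import (
    SimConfig,
    boundary_fixture,
    simulate_all,
    synthetic_topic_lexicon,
)

TRUST3 = ScaleDefinition(
    item_ids=("item_1", "item_2", "item_3"),
    reverse_flags=(False, False, True),
    response_min=1,
    response_max=5,
)


@pytest.fixture(scope="session")
def trust_scale():
    return TRUST3


@pytest.fixture(scope="session")
def small_sim():
    """One seeded synthetic draw shared across tests (200 users)."""
    config = SimConfig(n_users=200, n_communities=20)
    return simulate_all(config, seed=11)


@pytest.fixture(scope="session")
def topic_lexicon():
    return synthetic_topic_lexicon()


@pytest.fixture(scope="session")
def boundary():
    return boundary_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
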