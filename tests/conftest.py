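import warnings

import numpy as np
import pytest

from envnet.experiments import compute_metrics
from envnet.network_io import InteractionNetwork
from envnet.synthetic_data import ConfoundedSetSpec, generate_confounded_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net():
    return InteractionNetwork(
        id="tiny",
        incidence=np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0]]),
        interaction_class="mutualistic",
        sub_class="plant-pollinator",
        env={"temperature_variability": 3.0},
    )


def random_incidence(rng, m_range=(3, 8), n_range=(3, 8), p=0.4):
    """Random non-empty binary matrix for property tests."""
    while True:
        m = int(rng.integers(*m_range))
        n = int(rng.integers(*n_range))
        B = (rng.random((m, n)) < p).astype(np.int8)
        if B.sum() > 0:
            return B


@pytest.fixture(scope="session")
def small_confounded_set():
    """A reduced confounded community shared across tests (30/class)."""
    return generate_confounded_set(ConfoundedSetSpec(n_per_class=30, seed=424242))


@pytest.fixture(scope="session")
def small_metrics(small_confounded_set):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_metrics(small_confounded_set, R=50, seed=424243)
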