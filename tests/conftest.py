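import numpy as np
import pytest

from enceladus_niche import (
    SimConfig,
    clean_and_split,
    default_true_envelope,
    generate_layers,
    generate_occurrences,
)


@pytest.fixture(scope="session")
def small_stack():
    """A 40x40 four-variable synthetic world shared across tests."""
    cfg = SimConfig(shape=(40, 40), smoothness=3, seed=7)
    return generate_layers(cfg)


@pytest.fixture(scope="session")
def truth(small_stack):
    return default_true_envelope(small_stack)


@pytest.fixture(scope="session")
def occurrences(small_stack, truth):
    """300 noiseless occurrence records drawn from the true envelope."""
    return generate_occurrences(small_stack, truth, n=300, noise=0.0, seed=11)


@pytest.fixture(scope="session")
def occ_set(occurrences, small_stack):
    return clean_and_split(occurrences, small_stack, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
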