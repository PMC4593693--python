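import numpy as np
import pytest

from assocnet import (
    GeneratorConfig,
    counts_from_periods,
    generate_true_network,
    sample_observations,
)


@pytest.fixture(scope="session")
def clique_net():
    """A default 15-node clique-structured ground-truth network."""
    return generate_true_network(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def obs20(clique_net):
    """20 simulated sampling periods from the default network."""
    return sample_observations(clique_net, 20, seed=8)


@pytest.fixture(scope="session")
def counts20(obs20):
    return counts_from_periods(obs20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
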