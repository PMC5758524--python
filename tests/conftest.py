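import numpy as np
import pytest

from mutualnet import GeneratorConfig, generate_network
from mutualnet.datasets import galapagos_table1_network, toy_network


@pytest.fixture(scope="session")
def table1_net():
    """The 108 x 21 archipelago network reconstructed from group counts."""
    return galapagos_table1_network()


@pytest.fixture()
def toy_net():
    return toy_network()


@pytest.fixture()
def small_synthetic():
    """A small weighted coupled network for metric plumbing tests."""
    cfg = GeneratorConfig(
        n_plants=12, n_birds=8, fill_p=40, fill_s=25, coupling=0.3, seed=42
    )
    return generate_network(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
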