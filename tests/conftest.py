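import numpy as np
import pytest

from dbaae.aae import AAEConfig
from dbaae.preprocess import normalize
from dbaae.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def toy_counts():
    """Small separable six-group matrix (100 cells x 20 genes), no dropout."""
    config = SimulationConfig(
        n_genes=20, n_cells=100, n_groups=6, de_prob=0.4, seed=7
    )
    return simulate_counts(config)


@pytest.fixture(scope="session")
def toy_normalized(toy_counts):
    return normalize(toy_counts, n_top=20)


@pytest.fixture()
def tiny_model_config():
    """Very small architecture for fast unit tests."""
    return AAEConfig(
        input_dim=20,
        encoder_hidden=(16,),
        latent_dim=8,
        disc_hidden=(8,),
        learning_rate=1e-3,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
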