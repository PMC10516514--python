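import numpy as np
import pytest

from pepmhc import autodiff as ad
from pepmhc.model import Model, ModelConfig
from pepmhc.synthetic import SyntheticDatasetConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def float64_mode(monkeypatch):
    """Run autodiff in double precision (for finite-difference checks)."""
    monkeypatch.setattr(ad, "DTYPE", np.float64)


@pytest.fixture
def small_config():
    """A scaled-down model for fast structural/oracle tests."""
    return ModelConfig(
        model_length=15,
        embed_dim=6,
        kernel_spec={9: 4, 11: 3},
        fc_dims=[8, 5],
        dropout_rate=0.0,
    )


@pytest.fixture
def small_model(small_config):
    return Model(small_config, seed=1)


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact simulated dataset for training-behaviour tests."""
    config = SyntheticDatasetConfig(
        n_alleles=2,
        peptides_per_allele_per_length=40,
        lengths=(8, 9, 10, 11),
        seed=7,
    )
    return generate_dataset(config)
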