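"""Shared fixtures: small synthetic datasets and fast run configurations."""

import pytest

from methylcl.augmentation import AugmentationConfig
from methylcl.pipeline import RunConfig
from methylcl.synthetic import SyntheticConfig, generate_dataset
from methylcl.training import TrainConfig


def tiny_run_config(**overrides) -> RunConfig:
    """A deliberately small architecture/training setup for fast tests."""
    defaults = dict(
        k=3,
        seed=0,
        model=dict(conv_filters=8, hidden=8, proj_dim=8),
        training=TrainConfig(epochs=3, batch_size=16, patience=15, seed=0),
        augmentation=AugmentationConfig(),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture
def tiny_config():
    return tiny_run_config()


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 train / 20 test records with a fully penetrant planted motif."""
    cfg = SyntheticConfig(n_pos=40, n_neg=40, motif="GGACU", seed=5)
    return generate_dataset(cfg)
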