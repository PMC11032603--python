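import numpy as np
import pytest

from mirtarget.model import ModelConfig, TargetModel
from mirtarget.synthetic import SyntheticSpec, generate_pairs
from mirtarget.trainer import TrainConfig, train

#: small profile used by mechanics tests (not the recovery benchmark)
TINY_CONFIG = ModelConfig(d0=16, nl=1, nh=1, d1=8, ks=3, mirna_pad=24, cts_pad=66)


@pytest.fixture(scope="session")
def tiny_model() -> TargetModel:
    """An untrained (random but fixed-seed) tiny model in inference mode."""
    model = TargetModel(TINY_CONFIG, seed=99)
    model.eval()
    return model


@pytest.fixture(scope="session")
def tiny_checkpoint():
    """A quickly trained tiny checkpoint on a small separable pair set."""
    train_pairs = generate_pairs(SyntheticSpec(n_pairs=64, max_edits=0, rng_seed=21))
    val_pairs = generate_pairs(SyntheticSpec(n_pairs=24, max_edits=0, rng_seed=22))
    return train(train_pairs, val_pairs, TINY_CONFIG,
                 TrainConfig(epochs=3, batch_size=16, learning_rate=2e-3, rng_seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
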