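import numpy as np
import pytest

from hemamil import MilConfig
from hemamil.mil import init_params


def unpack_bags(pairs):
    """(features list, label array, evidence-flag list) from generator output."""
    X = [bag.features for bag, _ in pairs]
    y = np.asarray([bag.label for bag, _ in pairs])
    flags = [truth.evidence_flags for _, truth in pairs]
    return X, y, flags


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small dims so oracle loops stay fast."""
    return MilConfig(n_classes=3, input_dim=10, embed_dim=8, attn_dim=6,
                     dropout_p=0.0, B=2)


@pytest.fixture
def tiny_params(tiny_config, rng):
    return init_params(tiny_config, rng)
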