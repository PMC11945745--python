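import numpy as np
import pytest

from malnet.network import ModelConfig, init_params
from malnet.schema import (BINARY, CATEGORICAL, CONTINUOUS, FeatureDef,
                           FeatureSchema)


@pytest.fixture
def tiny_schema():
    """Three features (one of each kind), two labels; encoded width 5."""
    return FeatureSchema(
        features=(
            FeatureDef("age", CONTINUOUS),
            FeatureDef("fever", BINARY),
            FeatureDef("grade", CATEGORICAL, ("a", "b", "c")),
        ),
        label_names=("lab1", "lab2"),
    )


@pytest.fixture
def small_config():
    """A small architecture used for oracle and gradient tests."""
    return ModelConfig(token_dim=4, hidden_dim=4, n_heads=2, dropout_p=0.0,
                       n_labels=5, fc_dim=4)


@pytest.fixture
def small_params(small_config):
    return init_params(small_config, d=6, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
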