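from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tokengame import GameConfig, Variant

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def null_config():
    return GameConfig(variant=Variant.NULL, n_competitors=12, n_seasons=30, seed=0)


@pytest.fixture
def variant_configs(null_config):
    """The same n=12 all-pairs scenario under each feedback variant."""
    return {
        variant: replace(null_config, variant=variant) for variant in Variant
    }
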