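import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_table():
    """Well-separated two-class Gaussian feature clouds (Bayes error ~0.13%)."""
    from strokecad.fixtures import generate_feature_table

    return generate_feature_table([50, 50], n_features=5, separation=6.0, seed=11)
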