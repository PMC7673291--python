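import numpy as np
import pytest

from sporelife import GeneratorConfig


@pytest.fixture
def config():
    """Default generator configuration (the study conditions)."""
    return GeneratorConfig()


@pytest.fixture
def small_config():
    return GeneratorConfig(n_bags=60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
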