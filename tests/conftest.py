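import numpy as np
import pytest

from pblnet.pipeline import desk_synthetic_config, make_cases


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cases():
    """A handful of synthetic cases shared across fast tests."""
    return make_cases(6, desk_synthetic_config(0), seed=7)
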