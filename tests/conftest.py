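import numpy as np
import pytest

from tendrilcoil import ModelParams


@pytest.fixture
def params_nojitter():
    """Fully deterministic model parameters (no circumnutation drift)."""
    return ModelParams(jitter_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
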