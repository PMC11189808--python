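import numpy as np
import pytest

from rtsig import DEFAULT_PARAMS, make_reference


@pytest.fixture(scope="session")
def amplicon():
    """Default 200-nt amplicon with the m1A site at local position 100."""
    return make_reference(length=200, seed=1)


@pytest.fixture
def params_noerr():
    """Default RT-event model with sequencing error switched off."""
    return DEFAULT_PARAMS.with_(seq_error=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
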