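import numpy as np
import pytest
from hypothesis import settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # degenerate-network / empty-stream warnings are part of the contract and
    # asserted explicitly where relevant
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
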