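import numpy as np
import pytest

from tcpalm import DENDRA2, PhotophysicsParams


@pytest.fixture(scope="session")
def dendra2() -> PhotophysicsParams:
    """Measured Dendra2 rates with 60 ms frames."""
    return DENDRA2


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
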