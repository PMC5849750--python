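import numpy as np
import pytest

from taperlight import PRESETS


@pytest.fixture(scope="session")
def na066():
    return PRESETS["NA066"]


@pytest.fixture(scope="session")
def na039():
    return PRESETS["NA039"]


@pytest.fixture(scope="session")
def na022():
    return PRESETS["NA022"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
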