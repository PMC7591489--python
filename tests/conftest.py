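import numpy as np
import pytest

from nanocolloid import capping


@pytest.fixture(scope="session")
def citrate2():
    return capping.citrate_preset(2)


@pytest.fixture(scope="session")
def citrate3():
    return capping.citrate_preset(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
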