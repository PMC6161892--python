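import numpy as np
import pytest

from residyn import default_model, make_trial


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def trial():
    """One certified synthetic stride shared by read-only tests."""
    return make_trial(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
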