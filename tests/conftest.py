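import numpy as np
import pytest
from hypothesis import settings

from motimsg import make_default_database

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_db():
    return make_default_database()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
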