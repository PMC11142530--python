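import pytest

from shrimpgame import BASELINE
from shrimpgame.scenarios import sample_parameters


@pytest.fixture(scope="session")
def baseline():
    return BASELINE


@pytest.fixture(scope="session")
def batch100():
    """The 100-scenario seeded batch used by all sweep-based checks."""
    return sample_parameters(100, 42)
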