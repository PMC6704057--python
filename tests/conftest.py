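import numpy as np
import pytest

from memflex import CONTROL, KNOCKDOWN, ExperienceEvent, builtin_protocol


@pytest.fixture(scope="session")
def control():
    return CONTROL


@pytest.fixture(scope="session")
def knockdown():
    return KNOCKDOWN


@pytest.fixture(scope="session")
def nol_then_cfc():
    """Object-location task at 0 h, fear conditioning at 48 h."""
    return (ExperienceEvent("task1", 0.0), ExperienceEvent("task2", 48.0))


@pytest.fixture(scope="session")
def sequential_short():
    return builtin_protocol("sequential-short")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
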