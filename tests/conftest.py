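import numpy as np
import pytest

from npit import distributions as dist


@pytest.fixture(scope="session")
def case2():
    return dist.get_case(2)


@pytest.fixture(scope="session")
def case4():
    return dist.get_case(4)


@pytest.fixture
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(20240503)


@pytest.fixture
def normal_sample():
    """Standard-normal 1-D sample for generic estimator checks."""
    return np.random.default_rng(7).normal(size=(2000, 1))
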