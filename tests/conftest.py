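import numpy as np
import pytest

import mothmpc as m


@pytest.fixture(scope="session")
def params():
    return m.default_parameters()


@pytest.fixture(scope="session")
def ranges():
    return m.default_ranges()


@pytest.fixture(scope="session")
def goal_spec():
    return m.default_goal()


@pytest.fixture
def fa():
    return m.Treatment(actuation="fa")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
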