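import numpy as np
import pytest

from squaresloop.agent import AgentProfile
from squaresloop.task import TaskConfig


@pytest.fixture
def cfg():
    return TaskConfig()


@pytest.fixture
def cfg_high():
    return TaskConfig().with_condition("high", "high")


@pytest.fixture
def profile():
    return AgentProfile()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
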