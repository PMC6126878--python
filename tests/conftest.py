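import numpy as np
import pytest

from rml import ModelParams
from rml.tasks import Environment, Outcome


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


class ConstantRewardEnv(Environment):
    """Single-state env: every engaged choice is rewarded with magnitude R."""

    n_states = 1

    def __init__(self, R: float = 1.0, n_trials: int = 10_000):
        self.R = R
        self.n_trials = n_trials
        self.trial = -1

    def reset(self, rng):
        self.trial += 1
        return 0

    def costs(self, state):
        return np.zeros(3)

    def step(self, state, action, rng):
        if action == 2:
            return Outcome(r=0, R=0.0, next_state=None, cost=0.0)
        return Outcome(r=1, R=self.R, next_state=None, cost=0.0)


@pytest.fixture
def constant_reward_env():
    return ConstantRewardEnv()
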