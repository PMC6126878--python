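"""Task environments: probabilistic bandits, effort tasks, conditioning chains.

Every environment speaks the same protocol: ``reset`` yields the start
state of a trial, ``costs`` gives the per-action cost vector of a state,
and ``step`` consumes a (state, action) pair and returns an
:class:`Outcome` — reward presence ``r``, reward magnitude ``R``, the
successor state (``None`` marks a terminal transition) and the action
cost.  The last action index is always the "Stay" option: zero cost,
zero reward, immediate termination.

All schedules are generated internally from a seeded RNG; there is no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Outcome",
    "EnvironmentExhausted",
    "BanditSpec",
    "EffortSpec",
    "ChainSpec",
    "bandit_step",
    "effort_step",
    "chain_step",
    "Environment",
    "BanditEnv",
    "EffortEnv",
    "ChainEnv",
    "make_sim1_session",
    "REGIMES",
]

REGIMES = ("Stat", "Stat2", "Vol")


@dataclass(frozen=True)
class Outcome:
    """What one environment step returns."""

    r: int
    R: float
    next_state: Optional[int]
    cost: float

    def __post_init__(self) -> None:
        if self.r not in (0, 1):
            raise ValueError(f"r must be 0 or 1, got {self.r}")
        if self.R < 0 or self.cost < 0:
            raise ValueError("R and cost must be non-negative")


ZERO_OUTCOME = Outcome(r=0, R=0.0, next_state=None, cost=0.0)


class EnvironmentExhausted(RuntimeError):
    """Raised when stepping an environment past its trial budget."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


class BanditSpec(BaseModel):
    """A two-armed bandit block in one of three statistical regimes.

    ``Stat``: fixed 70/30 reward probabilities.  ``Stat2``: both arms 60%
    (maximal outcome noise, nothing to track).  ``Vol``: the
    probability->arm links permute at the trials listed in
    ``switch_schedule``.  Magnitudes are properties of the options and
    never move: the initial assignment gives the larger magnitude to the
    lower-probability option, and in every switch state the
    higher-probability option keeps the higher expected value, so reward
    probability is always the variable worth tracking.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    regime: Literal["Stat", "Stat2", "Vol"]
    probs: tuple[float, float]
    magnitudes: tuple[float, float]
    n_trials: int = 144
    switch_schedule: tuple[int, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "BanditSpec":
        for p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probabilities must be in [0, 1], got {self.probs}")
        if any(m < 0 for m in self.magnitudes):
            raise ValueError("magnitudes must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        # In every switch state the higher-probability option must carry
        # the higher expected value (probability is the relevant variable).
        parities = {self.n_switches_before(t) % 2 for t in range(self.n_trials)}
        for parity in parities:
            p = self.probs[::-1] if parity else self.probs
            if p[0] == p[1]:
                continue
            hi = int(np.argmax(p))
            if not p[hi] * self.magnitudes[hi] > p[1 - hi] * self.magnitudes[1 - hi]:
                raise ValueError(
                    "the higher-probability arm must have the higher expected value"
                )
        if any(t < 1 or t >= self.n_trials for t in self.switch_schedule):
            raise ValueError("switch trials must lie within 1..n_trials-1")
        if self.regime != "Vol" and self.switch_schedule:
            raise ValueError("only Vol blocks may carry a switch schedule")
        return self

    # -- canonical regimes -------------------------------------------------

    @classmethod
    def stat(cls, n_trials: int = 144) -> "BanditSpec":
        return cls(regime="Stat", probs=(0.7, 0.3), magnitudes=(1.0, 1.5), n_trials=n_trials)

    @classmethod
    def stat2(cls, n_trials: int = 144) -> "BanditSpec":
        return cls(regime="Stat2", probs=(0.6, 0.6), magnitudes=(1.0, 1.5), n_trials=n_trials)

    @classmethod
    def vol(
        cls,
        rng: np.random.Generator,
        n_trials: int = 144,
        switch_period: int = 30,
    ) -> "BanditSpec":
        """Volatile block: permutation every ``switch_period`` trials,
        first switch at a uniformly drawn offset."""
        first = int(rng.integers(1, switch_period + 1))
        schedule = tuple(range(first, n_trials, switch_period))
        return cls(
            regime="Vol",
            probs=(0.7, 0.3),
            magnitudes=(1.0, 1.5),
            n_trials=n_trials,
            switch_schedule=schedule,
        )

    # -- schedule queries --------------------------------------------------

    def n_switches_before(self, trial: int) -> int:
        return sum(1 for t in self.switch_schedule if t <= trial)

    def current_probs(self, trial: int) -> tuple[float, float]:
        """Per-arm reward probabilities in force at ``trial`` (0-based)."""
        if self.n_switches_before(trial) % 2 == 1:
            return self.probs[::-1]  # type: ignore[return-value]
        return self.probs

    def high_arm(self, trial: int) -> Optional[int]:
        """Arm with the higher reward probability (and, by the validated
        construction, the higher expected value) at ``trial``; ``None``
        when the probabilities tie and there is no optimal choice."""
        p = self.current_probs(trial)
        if p[0] == p[1]:
            return None
        return int(np.argmax(p))


class EffortSpec(BaseModel):
    """Two-option effort/reward trade-off task.

    ``Effort``: the high-reward (HR) option costs a high effort, the
    low-reward (LR) option a low effort.  ``NoEffort``: both options are
    cheap.  ``DoubleEffort``: both are expensive.  Rewards are delivered
    deterministically for engaged choices; "Stay" yields nothing at no
    cost.  Action indices: 0 = HR, 1 = LR, 2 = Stay.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    variant: Literal["Effort", "NoEffort", "DoubleEffort"] = "Effort"
    hr_magnitude: float = 1.0
    lr_magnitude: float = 0.4
    high_cost: float = 2.0
    low_cost: float = 0.2
    n_trials: int = 150

    @model_validator(mode="after")
    def _check(self) -> "EffortSpec":
        if not self.hr_magnitude > self.lr_magnitude >= 0:
            raise ValueError("need hr_magnitude > lr_magnitude >= 0")
        if not self.high_cost >= self.low_cost >= 0:
            raise ValueError("need high_cost >= low_cost >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        return self

    @property
    def option_costs(self) -> tuple[float, float]:
        if self.variant == "Effort":
            return (self.high_cost, self.low_cost)
        if self.variant == "NoEffort":
            return (self.low_cost, self.low_cost)
        return (self.high_cost, self.high_cost)


class ChainSpec(BaseModel):
    """Higher-order conditioning chain / binary-choice maze.

    States are indexed by conditioning order minus one: state 0 is the
    first-order cue (adjacent to primary reward), state ``depth - 1`` is
    the trial's start cue (furthest from reward).  Classical chains
    advance regardless of the action; the instrumental maze advances only
    on the correct branch and terminates unrewarded on a wrong branch or
    on "Stay".  Transitions are deterministic and the terminal reward
    rate is 100% on the correct path, 0% otherwise.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    paradigm: Literal["classical", "instrumental"]
    depth: int = 1
    max_order: int = 3
    reward_magnitude: float = 1.0
    #: correct branch per state (instrumental only), length ``max_order``.
    correct_actions: tuple[int, ...] = (0, 0, 0)
    n_trials: int = 100

    @model_validator(mode="after")
    def _check(self) -> "ChainSpec":
        if not (1 <= self.depth <= self.max_order):
            raise ValueError("depth must lie in 1..max_order")
        if len(self.correct_actions) != self.max_order:
            raise ValueError("correct_actions must have length max_order")
        if any(a not in (0, 1) for a in self.correct_actions):
            raise ValueError("correct actions must be motor actions 0 or 1")
        if self.reward_magnitude < 0:
            raise ValueError("reward_magnitude must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Functional steppers
# ---------------------------------------------------------------------------


def bandit_step(spec: BanditSpec, trial: int, action: int, rng: np.random.Generator) -> Outcome:
    """One bandit choice.  Rewards are Bernoulli draws at the arm's
    current probability; bandit choices are low-effort (cost 0)."""
    if trial >= spec.n_trials:
        raise EnvironmentExhausted(f"trial {trial} beyond block length {spec.n_trials}")
    if action not in (0, 1, 2):
        raise ValueError(f"invalid bandit action {action}")
    if action == 2:  # Stay
        return ZERO_OUTCOME
    p = spec.current_probs(trial)[action]
    m = spec.magnitudes[action]
    r = int(rng.random() < p)
    return Outcome(r=r, R=m if r else 0.0, next_state=None, cost=0.0)


def effort_step(spec: EffortSpec, action: int, rng: np.random.Generator) -> Outcome:
    """One effort-task choice.  Engaged choices pay their effort cost and
    deterministically deliver their option's reward magnitude."""
    if action not in (0, 1, 2):
        raise ValueError(f"invalid effort-task action {action}")
    if action == 2:  # Stay
        return ZERO_OUTCOME
    magnitude = spec.hr_magnitude if action == 0 else spec.lr_magnitude
    return Outcome(r=1, R=magnitude, next_state=None, cost=spec.option_costs[action])


def chain_step(spec: ChainSpec, state: int, action: int, rng: np.random.Generator) -> Outcome:
    """One transition of a conditioning chain or maze."""
    if not (0 <= state < spec.depth):
        raise ValueError(f"state {state} outside chain of depth {spec.depth}")
    if spec.paradigm == "classical":
        advance = True  # passive paradigm: the action is ignored
    else:
        advance = action == spec.correct_actions[state]
    if not advance:
        return ZERO_OUTCOME
    if state == 0:
        return Outcome(r=1, R=spec.reward_magnitude, next_state=None, cost=0.0)
    return Outcome(r=0, R=0.0, next_state=state - 1, cost=0.0)


# ---------------------------------------------------------------------------
# Stateful environment wrappers (what the agent's trial loop consumes)
# ---------------------------------------------------------------------------


class Environment:
    """Minimal environment protocol; subclasses own the trial counter."""

    n_states: int
    n_actions: int = 3

    def reset(self, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def costs(self, state: int) -> np.ndarray:
        raise NotImplementedError

    def step(self, state: int, action: int, rng: np.random.Generator) -> Outcome:
        raise NotImplementedError


class BanditEnv(Environment):
    """Single-state wrapper around :func:`bandit_step`."""

    n_states = 1

    def __init__(self, spec: BanditSpec):
        self.spec = spec
        self.trial = -1

    def reset(self, rng: np.random.Generator) -> int:
        self.trial += 1
        if self.trial >= self.spec.n_trials:
            raise EnvironmentExhausted("bandit block exhausted")
        return 0

    def costs(self, state: int) -> np.ndarray:
        return np.zeros(3)

    def step(self, state: int, action: int, rng: np.random.Generator) -> Outcome:
        return bandit_step(self.spec, self.trial, action, rng)

    def high_arm(self) -> Optional[int]:
        return self.spec.high_arm(self.trial)


class EffortEnv(Environment):
    """Single-state wrapper around :func:`effort_step`."""

    n_states = 1

    def __init__(self, spec: EffortSpec):
        self.spec = spec
        self.trial = -1

    def reset(self, rng: np.random.Generator) -> int:
        self.trial += 1
        if self.trial >= self.spec.n_trials:
            raise EnvironmentExhausted("effort block exhausted")
        return 0

    def costs(self, state: int) -> np.ndarray:
        c = self.spec.option_costs
        return np.array([c[0], c[1], 0.0])

    def step(self, state: int, action: int, rng: np.random.Generator) -> Outcome:
        return effort_step(self.spec, action, rng)


class ChainEnv(Environment):
    """Wrapper around :func:`chain_step`; trials start at the deepest cue."""

    def __init__(self, spec: ChainSpec):
        self.spec = spec
        self.n_states = spec.max_order
        self.trial = -1

    def reset(self, rng: np.random.Generator) -> int:
        self.trial += 1
        if self.trial >= self.spec.n_trials:
            raise EnvironmentExhausted("chain block exhausted")
        return self.spec.depth - 1

    def costs(self, state: int) -> np.ndarray:
        return np.zeros(3)

    def step(self, state: int, action: int, rng: np.random.Generator) -> Outcome:
        return chain_step(self.spec, state, action, rng)


# ---------------------------------------------------------------------------
# Session builders
# ---------------------------------------------------------------------------


def make_sim1_session(
    n_trials: int = 432,
    order: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[BanditSpec]:
    """Build the three-regime bandit session: ``n_trials`` split equally
    into one block per statistical regime, in the given (or randomized)
    order; the volatile block carries its switch schedule."""
    if n_trials % 3 != 0:
        raise ValueError(f"n_trials must be divisible by 3, got {n_trials}")
    rng = rng if rng is not None else np.random.default_rng()
    if order is None:
        order = [REGIMES[i] for i in rng.permutation(3)]
    if sorted(order) != sorted(REGIMES):
        raise ValueError(f"order must be a permutation of {REGIMES}, got {tuple(order)}")
    block = n_trials // 3
    builders = {
        "Stat": lambda: BanditSpec.stat(block),
        "Stat2": lambda: BanditSpec.stat2(block),
        "Vol": lambda: BanditSpec.vol(rng, block),
    }
    return [builders[regime]() for regime in order]
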