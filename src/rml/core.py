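"""The agent: value stores, module equations, lesion gains, trial loop.

Four modules cooperate on every trial:

* **dACC_Act** — an actor-critic over environmental states and motor
  actions.  The critic keeps a state/action value table ``v`` updated by
  a delta rule toward the dopaminergic teaching signal; the actor draws
  the action from a softmax over cost-discounted values.
* **dACC_Boost** — an actor-critic over discrete boosting levels
  ``b in 1..n_boost_levels``.  Its value table ``v_B`` is updated from a
  second dopaminergic signal that charges the boosting cost.
* **VTA** — computes both dopamine signals: the action-learning signal
  ``DA = r(R + mu*b) + b(1-mu)*rho*max_a v(s', a)`` and the boost-learning
  signal ``DA_B = r(da_gain*R - omega*b)``.
* **LC** — sets the norepinephrine level ``NE = b`` (which divides action
  costs in the policy) and runs one adaptive learning-rate filter per
  dACC module, approximating a Kalman gain from the value and
  prediction-error time series.

Lesions are multiplicative gains: ``da_gain`` on the VTA outputs,
``dacc_gain`` on every dACC value readout (policy inputs and the
expectation/PE signals sent to the brainstem).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .params import INTACT, LesionSpec, ModelParams
from .tasks import Environment, Outcome

__all__ = [
    "softmax_policy",
    "action_preferences",
    "update_value",
    "RateFilterState",
    "update_rate_filter",
    "compute_da_act",
    "compute_da_boost",
    "TrialRecord",
    "ValueStores",
    "MetaLearner",
]


def softmax_policy(values: np.ndarray, tau: float) -> np.ndarray:
    """Softmax distribution ``exp(x_i/tau) / sum_j exp(x_j/tau)``.

    Numerically stabilised by subtracting the max, which leaves the
    distribution unchanged (translation invariance).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-d vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if not (np.isfinite(tau) and tau > 0.0):
        raise ValueError(f"tau must be a positive finite number, got {tau}")
    z = (values - values.max()) / tau
    e = np.exp(z)
    return e / e.sum()


def action_preferences(
    v_row: np.ndarray,
    costs: np.ndarray,
    ne: float,
    dacc_gain: float = 1.0,
) -> np.ndarray:
    """Cost-discounted action preferences ``dacc_gain*v - C/NE``.

    Norepinephrine divides the action costs: a high NE level lowers the
    perceived cost of effortful actions, energizing behaviour.  ``ne``
    equals the boosting level chosen on the current trial and is always
    at least 1.
    """
    v_row = np.asarray(v_row, dtype=float)
    costs = np.asarray(costs, dtype=float)
    if v_row.shape != costs.shape:
        raise ValueError("v_row and costs must have the same shape")
    if not np.isfinite(ne) or ne < 1.0:
        raise ValueError(f"ne must be >= 1, got {ne}")
    if np.any(costs < 0):
        raise ValueError("costs must be non-negative")
    return dacc_gain * v_row - costs / ne


def update_value(old_v: float, signal: float, lam: float, beta: float) -> tuple[float, float]:
    """Delta-rule update toward a teaching signal.

    Returns ``(new_value, prediction_error)`` where
    ``new_value = old_v + lam * (signal - old_v)``.
    """
    if not (beta <= lam <= 1.0):
        raise ValueError(f"lam must lie in [beta={beta}, 1], got {lam}")
    if not (np.isfinite(old_v) and np.isfinite(signal)):
        raise ValueError("old_v and signal must be finite")
    pe = signal - old_v
    return old_v + lam * pe, pe


@dataclass(frozen=True)
class RateFilterState:
    """Running state of one LC learning-rate filter.

    ``v_hat`` low-pass tracks the currently-updated value, ``delta_hat``
    low-pass tracks the unsigned prediction error, and ``lam`` is the
    resulting learning rate, clamped to ``[beta, 1]``.
    """

    v_hat: float = 0.0
    delta_hat: float = 0.0
    lam: float = 0.2

    @classmethod
    def initial(cls, beta: float) -> "RateFilterState":
        return cls(v_hat=0.0, delta_hat=0.0, lam=beta)


def update_rate_filter(
    state: RateFilterState,
    v_now: float,
    delta_now: float,
    alpha: float,
    beta: float,
) -> RateFilterState:
    """One step of the approximate-Kalman learning-rate filter.

    The filter estimates process variance as the squared displacement of
    the tracked value from its own low-pass estimate, total variance as
    the squared low-passed unsigned PE, and sets the learning rate to
    their ratio (the Kalman-gain analogue), clamped to ``[beta, 1]``:

    1. ``var = (v_now - v_hat_prev)**2``        (pre-update ``v_hat``)
    2. ``v_hat     += alpha * (v_now - v_hat_prev)``
    3. ``delta_hat += alpha * (|delta_now| - delta_hat_prev)``
    4. ``lam = clip(var / delta_hat**2, beta, 1)``

    A vanishing ``delta_hat`` never divides: the clamp resolves it to 1
    when ``var`` is genuinely positive and to ``beta`` when ``var`` is
    zero up to floating-point residue (a constant tracked value keeps the
    rate at its floor).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (np.isfinite(v_now) and np.isfinite(delta_now)):
        raise ValueError("filter inputs must be finite")
    var = (v_now - state.v_hat) ** 2
    v_hat = state.v_hat + alpha * (v_now - state.v_hat)
    delta_hat = state.delta_hat + alpha * (abs(delta_now) - state.delta_hat)
    denom = delta_hat**2
    if denom == 0.0:
        lam = 1.0 if var > 1e-12 else beta
    else:
        lam = min(1.0, max(beta, var / denom))
    return RateFilterState(v_hat=v_hat, delta_hat=delta_hat, lam=lam)


def compute_da_act(
    r: int,
    R: float,
    b: int,
    max_next_v: float,
    params: ModelParams,
    da_gain: float = 1.0,
) -> float:
    """Dopaminergic teaching signal for the action module.

    ``da_gain * [ r*(R + mu*b) + b*(1-mu)*rho*max_next_v ]`` — the first
    term is the boost-amplified primary reward, the second the
    boost-amplified TD (non-primary reward) term carrying successor
    value.  At terminal states ``max_next_v`` is 0, and with ``mu = 0``
    the expression reduces to the standard Q-learning target.
    """
    if r not in (0, 1):
        raise ValueError(f"r must be 0 or 1, got {r}")
    if b < 1:
        raise ValueError(f"b must be >= 1, got {b}")
    if not (np.isfinite(R) and np.isfinite(max_next_v)):
        raise ValueError("R and max_next_v must be finite")
    p = params
    return da_gain * (r * (R + p.mu * b) + b * (1.0 - p.mu) * p.rho * max_next_v)


def compute_da_boost(r: int, R: float, b: int, omega: float, da_gain: float = 1.0) -> float:
    """Dopaminergic teaching signal for the boost module.

    ``r * (da_gain*R - omega*b)``: the reward magnitude discounted by the
    boosting cost, charged only on reward-presence steps.  A dopamine
    lesion attenuates the reward component transmitted by the VTA; the
    boosting cost itself is not attenuated, so a lesioned agent faces an
    unchanged cost against a weakened benefit.
    """
    if r not in (0, 1):
        raise ValueError(f"r must be 0 or 1, got {r}")
    if b < 1:
        raise ValueError(f"b must be >= 1, got {b}")
    return r * (da_gain * R - omega * b)


@dataclass(frozen=True)
class TrialRecord:
    """Full per-step trace of one agent-environment interaction.

    One record per environment step; single-step tasks (bandits, effort
    tasks) produce exactly one record per trial.  ``da_b``, ``pe_boost``
    and ``lam_boost`` are populated on the final step of an episode
    (where the boost-value update happens) and are NaN elsewhere.
    """

    trial_index: int
    step_index: int
    state: int
    boost: int
    ne: float
    action: int
    outcome: Outcome
    da: float
    da_b: float
    pe_act: float
    pe_boost: float
    lam_act: float
    lam_boost: float
    #: dacc-scaled max_a v(state, a) at entry, before this step's update.
    state_max_v: float
    #: dacc-scaled max_a v(next_state, a); 0 at terminal transitions.
    next_max_v: float


@dataclass
class ValueStores:
    """Action-value table ``v[s, a]`` and boost-value table ``v_B[s, b]``."""

    v: np.ndarray
    v_b: np.ndarray

    @classmethod
    def zeros(cls, n_states: int, n_actions: int, n_boost_levels: int) -> "ValueStores":
        return cls(
            v=np.zeros((n_states, n_actions)),
            v_b=np.zeros((n_states, n_boost_levels)),
        )


class MetaLearner:
    """The discrete meta-learning agent.

    Parameters
    ----------
    params
        Fixed scalar parameters (defaults are the canonical set).
    n_states
        Number of environmental states the value tables cover.
    lesion
        Multiplicative gains on VTA / dACC outputs; default intact.
    rng
        A ``numpy.random.Generator``; required for sampling policies.
    clamp_boost
        If set, boost selection is disabled and ``b`` is clamped at the
        given level on every trial (the boost-value table and its
        learning-rate filter are then frozen).
    """

    def __init__(
        self,
        params: ModelParams | None = None,
        n_states: int = 3,
        lesion: LesionSpec | None = None,
        rng: np.random.Generator | None = None,
        clamp_boost: Optional[int] = None,
    ):
        self.params = params or ModelParams()
        self.lesion = lesion or INTACT
        self.rng = rng if rng is not None else np.random.default_rng()
        if clamp_boost is not None and not (1 <= clamp_boost <= self.params.n_boost_levels):
            raise ValueError(f"clamp_boost must be in 1..{self.params.n_boost_levels}")
        self.clamp_boost = clamp_boost
        self.stores = ValueStores.zeros(n_states, self.params.n_actions, self.params.n_boost_levels)
        # The LC keeps the (v_hat, delta_hat) statistics per value entry —
        # each value series is its own Kalman-style tracking problem — and
        # emits one module-level learning rate per trial: the one computed
        # for the entry currently being updated.  Pooling the statistics
        # across entries would read the policy's alternation between
        # actions of different value as process variance, swamping the
        # volatility signal the filter exists to detect.
        beta = self.params.beta
        self.act_filters = [
            [RateFilterState.initial(beta) for _ in range(self.params.n_actions)]
            for _ in range(n_states)
        ]
        self.boost_filters = [
            [RateFilterState.initial(beta) for _ in range(self.params.n_boost_levels)]
            for _ in range(n_states)
        ]
        self._trial_count = 0

    # -- readouts ----------------------------------------------------------

    def _v_readout(self, state: int) -> np.ndarray:
        """dACC value readout for a state (lesion gain applied)."""
        return self.lesion.dacc_gain * self.stores.v[state]

    def _max_v(self, state: Optional[int]) -> float:
        """Scaled max_a v(state, a); 0 for terminal (None) states."""
        if state is None:
            return 0.0
        return float(self._v_readout(state).max())

    # -- policies ----------------------------------------------------------

    def select_boost(self, state: int) -> int:
        """Sample a boosting level from the softmax over boost values."""
        if self.clamp_boost is not None:
            return self.clamp_boost
        prefs = self.lesion.dacc_gain * self.stores.v_b[state]
        probs = softmax_policy(prefs, self.params.tau)
        return int(self.rng.choice(self.params.n_boost_levels, p=probs)) + 1

    def select_action(self, state: int, costs: np.ndarray, ne: float) -> int:
        prefs = action_preferences(self.stores.v[state], costs, ne, self.lesion.dacc_gain)
        probs = softmax_policy(prefs, self.params.tau)
        return int(self.rng.choice(self.params.n_actions, p=probs))

    # -- trial loop --------------------------------------------------------

    def run_trial(self, env: Environment) -> list[TrialRecord]:
        """Run one trial (episode) and return its per-step records.

        Fixed within-trial order: observe the start state; the boost
        module samples ``b``; ``NE := b``; then on each step the action
        module samples an action from cost-discounted values, the
        environment returns an outcome, the VTA computes the teaching
        signals, the LC filters update the learning rates, and the value
        stores are updated with the current-trial learning rates.  The
        boost value of the start state is updated once, from the final
        outcome of the episode.
        """
        p = self.params
        les = self.lesion
        trial = self._trial_count
        self._trial_count += 1

        start_state = env.reset(self.rng)
        b = self.select_boost(start_state)
        ne = float(b)

        records: list[TrialRecord] = []
        state: Optional[int] = start_state
        outcome: Optional[Outcome] = None
        step = 0
        while state is not None:
            costs = env.costs(state)
            action = self.select_action(state, costs, ne)
            outcome = env.step(state, action, self.rng)
            state_max = self._max_v(state)
            next_max = self._max_v(outcome.next_state)

            da = compute_da_act(outcome.r, outcome.R, b, next_max, p, les.da_gain)
            # The lesion attenuates what the module EMITS (the value
            # readout and the PE signal exported to the brainstem), not
            # the plasticity itself: the delta rule drives the internal
            # value toward the teaching signal, so an attenuated module
            # cannot silently re-inflate its stored values to compensate.
            pe_internal = da - self.stores.v[state, action]
            v_read = les.dacc_gain * self.stores.v[state, action]
            pe = les.dacc_gain * pe_internal
            self.act_filters[state][action] = update_rate_filter(
                self.act_filters[state][action], v_read, pe, p.alpha, p.beta
            )
            lam = self.act_filters[state][action].lam
            self.stores.v[state, action] += lam * pe_internal

            records.append(
                TrialRecord(
                    trial_index=trial,
                    step_index=step,
                    state=state,
                    boost=b,
                    ne=ne,
                    action=action,
                    outcome=outcome,
                    da=da,
                    da_b=np.nan,
                    pe_act=pe,
                    pe_boost=np.nan,
                    lam_act=lam,
                    lam_boost=np.nan,
                    state_max_v=state_max,
                    next_max_v=next_max,
                )
            )
            state = outcome.next_state
            step += 1

        # Boost-value update from the episode's final outcome.
        assert outcome is not None
        da_b = compute_da_boost(outcome.r, outcome.R, b, p.omega, les.da_gain)
        if self.clamp_boost is None:
            pe_b_internal = da_b - self.stores.v_b[start_state, b - 1]
            vb_read = les.dacc_gain * self.stores.v_b[start_state, b - 1]
            pe_b = les.dacc_gain * pe_b_internal
            self.boost_filters[start_state][b - 1] = update_rate_filter(
                self.boost_filters[start_state][b - 1], vb_read, pe_b, p.alpha, p.beta
            )
            lam_b = self.boost_filters[start_state][b - 1].lam
            self.stores.v_b[start_state, b - 1] += lam_b * pe_b_internal
        else:
            pe_b, lam_b = np.nan, np.nan

        last = records[-1]
        records[-1] = replace(last, da_b=da_b, pe_boost=pe_b, lam_boost=lam_b)
        return records
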