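"""Model parameters and lesion specifications.

The agent is governed by six scalar parameters shared across every task
(one fixed parameter set; no per-task tuning):

========  =======  ====================================================
symbol    default  meaning
========  =======  ====================================================
rho       0.2      TD discount on the non-primary (successor-value) term
mu        0.1      split of the boost modulation between primary and
                   non-primary reward components of the dopamine signal
tau       0.6      softmax temperature (both action and boost selection)
alpha     0.3      low-pass constant of the learning-rate filter
beta      0.2      learning-rate floor (lambda is clamped to [beta, 1])
omega     0.15     cost per unit of catecholamine boosting
========  =======  ====================================================

Structurally the agent has ``n_actions`` motor actions per state — the
last one is always the zero-cost, zero-reward "Stay" option — and
``n_boost_levels`` discrete boosting actions (integers ``1..10``).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["ModelParams", "LesionSpec", "STAY"]

#: Conventional index of the "Stay" (disengage) action: always the last one.
STAY = -1


class ModelParams(BaseModel):
    """The fixed scalar parameters plus structural constants of the agent."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    rho: float = 0.2
    mu: float = 0.1
    tau: float = 0.6
    alpha: float = 0.3
    beta: float = 0.2
    omega: float = 0.15
    n_boost_levels: int = 10
    n_actions: int = 3

    @model_validator(mode="after")
    def _check_ranges(self) -> "ModelParams":
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if not (self.tau > 0.0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not (self.omega >= 0.0):
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.n_boost_levels < 1:
            raise ValueError("n_boost_levels must be >= 1")
        if self.n_actions < 2:
            raise ValueError("n_actions must be >= 2 (one motor action plus Stay)")
        return self


class LesionSpec(BaseModel):
    """Multiplicative attenuation of module outputs.

    ``da_gain`` scales every VTA output (the dopaminergic teaching
    signals); ``dacc_gain`` scales every dACC activation — the value
    readouts entering both softmaxes and the expectation/PE signals sent
    to the LC and VTA. ``(1, 1)`` is the intact agent.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    da_gain: float = 1.0
    dacc_gain: float = 1.0

    @model_validator(mode="after")
    def _check_gains(self) -> "LesionSpec":
        for name in ("da_gain", "dacc_gain"):
            g = getattr(self, name)
            if not (0.0 < g <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {g}")
        return self

    @property
    def intact(self) -> bool:
        return self.da_gain == 1.0 and self.dacc_gain == 1.0


#: Canonical lesion batteries used throughout the experiments.
INTACT = LesionSpec()
DA_LESION = LesionSpec(da_gain=0.5)
DACC_LESION = LesionSpec(dacc_gain=0.5)
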