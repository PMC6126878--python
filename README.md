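# rml — a discrete reinforcement meta-learner

`rml` simulates a four-module actor-critic agent in which a cortical
decision system recurrently controls its own brainstem neuromodulation.
Two "dACC" modules do the deciding: one selects motor actions toward the
environment, the other selects a discrete *boosting* level
`b ∈ {1, …, 10}` that scales catecholamine release.  Two brainstem
modules close the loop: a dopaminergic ("VTA") module computes the
teaching signals both critics learn from, and a noradrenergic ("LC")
module turns the boost into an effort discount (`NE = b`) and sets both
critics' learning rates adaptively, approximating a Kalman gain.  The
package is for computational-neuroscience researchers who want to study
meta-learning of learning rate, effort allocation and intrinsic
motivation — and what dopamine or cingulate lesions do to them — in a
fully reproducible, trial-discrete setting.

## Model

State/action values follow a delta rule toward the dopamine signal,

    Δv_t(s, a) = λ_t · (DA_t − v_{t−1}(s, a)),

with actions drawn from a softmax over cost-discounted values,

    p(a | s) = softmax( v(s, a) − C(s, a) / NE , τ ),

so high norepinephrine lowers perceived effort costs.  The dopamine
signal mixes primary and non-primary (TD) reward, both amplified by the
boost,

    DA_t = r_t (R + μ b) + b (1 − μ) ρ · max_a v_t(s′, a),

which at `μ = 0`, `b = 1` is the familiar Q-learning target.  The boost
itself is learned by a second critic from a cost-discounted dopamine
signal `DA_B,t = r_t (R − ω b)`: boosting energizes behaviour but costs
`ω` per unit.  Learning rates are set per module each trial by

    λ_t = Var̂(v)_t / δ̂_t² ,   β ≤ λ ≤ 1,

where `Var̂(v) = (v_t − v̂_{t−1})²` and `v̂`, `δ̂` are running low-pass
estimates (rate `α`) of the tracked value and the unsigned prediction
error — an approximate Kalman gain that rises under genuine volatility
and stays at the floor `β` under mere noise.  One fixed parameter set
(ρ=0.2, μ=0.1, τ=0.6, α=0.3, β=0.2, ω=0.15) is used for every task.

Lesions are multiplicative gains: `da_gain` attenuates every VTA output,
`dacc_gain` attenuates everything the cortical modules emit (policy
readouts and the value/PE signals sent to the brainstem).

Task environments are generated internally: a three-regime two-armed
bandit (stationary 70/30, stationary-uncertain 60/60, and volatile with
permuting probability→option links), effort/reward trade-off tasks
(Effort, NoEffort, DoubleEffort, plus an always-available zero-cost
"Stay" option), and higher-order conditioning chains — passive classical
cue sequences and a three-level instrumental binary-choice maze.

## Worked example

```bash
rml sim1 --subjects 12 --seed 1
```

runs 12 agents through the 432-trial three-regime bandit session and
prints the per-regime cohort means:

```
        mean_lambda  mean_abs_pe  accuracy_all  engaged_frac  mean_boost  n_trials  accuracy
regime
Stat       0.231942     0.628614      0.567130      0.876736    4.686343     144.0  0.646425
Stat2      0.218710     0.777438           NaN      0.902778    4.549190     144.0       NaN
Vol        0.239842     0.738871      0.546875      0.888889    4.786458     144.0  0.614544
```

Read-out: the learning rate `mean_lambda` is highest in the volatile
block (0.240) and lowest in the noisy-but-stationary block (0.219) — the
agent raises plasticity only for genuine change, not for noise — while
the mean unsigned prediction error (`mean_abs_pe`, the cortical activity
proxy) peaks in the noisy block instead: the two uncertainty signals
dissociate.  `accuracy` is the fraction of engaged choices that picked
the currently better arm (64.6% stationary, 61.5% volatile; the 60/60
block has no better arm).

Other subcommands: `rml sim2a` (effort battery across intact,
DA-lesioned and dACC-lesioned cohorts), `rml sim2b` (recovery after the
lesion), `rml sim3` (classical vs instrumental higher-order
conditioning), `rml sweep` (clamped-boost cost/benefit curves), plus
`validate-config` and `version`.  Every subcommand accepts
`--config PATH --seed INT --subjects INT --out DIR`; with `--out` it
writes per-subject trial CSVs, a summary JSON, a config echo and a
checksum manifest.  The same protocols are available as library calls
(`rml.run_simulation1`, `rml.boost_sweep`, …), each returning the full
per-trial log alongside the per-subject summaries.

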