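# Methods

## The agent

The agent is a pair of actor-critic learners sharing one brainstem.
Per trial (episode) the order of operations is fixed:

1. observe the start state `s`;
2. the boost module samples `b ∈ {1..10}` from
   `softmax(g_dACC · v_B(s, ·), τ)`; boosting can instead be clamped for
   cost/benefit sweeps, which freezes boost learning;
3. the norepinephrine level is set to the boost, `NE = b`, for the whole
   episode (any monotone map would do; the identity is the simplest);
4. on each step the action module samples from
   `softmax(g_dACC · v(s, ·) − C(s, ·)/NE, τ)`; the last action is
   always "Stay": zero cost, zero reward, immediate termination;
5. the environment returns `(r, R, s′, cost)`;
6. the dopamine signals are computed:
   `DA = g_DA · [ r(R + μb) + b(1−μ)ρ · g_dACC · max_a v(s′, a) ]`
   (the successor-value expectation is a cortical readout, hence carries
   `g_dACC`; `max v ≡ 0` at terminal transitions), and, once per
   episode from the final outcome, `DA_B = r (g_DA · R − ω b)`;
7. prediction errors and learning rates are updated (below), then the
   value stores: `v(s,a) += λ · (DA − v(s,a))`, and
   `v_B(s₀,b) += λ_B · (DA_B − v_B(s₀,b))` keyed to the episode's start
   state.

### Learning-rate filter

Each value entry keeps two running statistics, updated only when that
entry is trained: a low-pass of its value, `v̂ += α(v − v̂)`, and a
low-pass of its unsigned prediction error, `δ̂ += α(|δ| − δ̂)`.  The
learning rate emitted on a trial is

    λ = clip( (v − v̂_prev)² / δ̂² , β, 1 )

computed from the pre-update `v̂` of the entry being trained.  The
numerator estimates process variance (systematic drift of the estimate
away from its own slow average), the denominator total variance; their
ratio approximates a Kalman gain.  `α` encodes the single structural
assumption that noise fluctuates faster than genuine environmental
change.  When `δ̂ = 0` the clip resolves the ratio without dividing:
λ = 1 for a genuinely positive numerator, β when the numerator is zero
up to floating-point residue (threshold 1e−12), so a constant,
perfectly predicted value keeps the rate at its floor.

Keeping the statistics per entry (rather than pooled per module) is a
deliberate choice: pooled statistics read the policy's alternation
between actions of different value as process variance, which inflates λ
everywhere and buries the volatility signal — empirically it inverts the
volatile-vs-stationary λ ordering.  The λ *reported* per trial is still
a single module-level number: that of the entry being trained.

### Boost timing

The boost is selected once per episode and its value updated once, from
the episode's final outcome.  The alternative — reselecting `b` at every
step — would charge the `ω b` cost only on reward-presence steps, so the
boost values of all reward-distal states would never differentiate and
the classical/instrumental boosting contrast could not arise.  One boost
per trial also matches the one-value-per-trial boosting time courses the
model is meant to produce.

### Lesions

A lesion is a multiplicative gain in (0, 1], default 0.5 when applied.
`da_gain` scales every VTA output.  `dacc_gain` scales everything the
cortical modules *emit*: the value readouts entering both softmaxes, the
successor-value expectation sent to the dopamine module, and the
value/PE signals sent to the learning-rate filter.  Plasticity itself
operates on the internal (unscaled) values.  This matters: if the delta
rule consumed the attenuated expectation, the store would converge to
`DA / g` and the attenuated readout would exactly cancel the lesion,
leaving behaviour intact — attenuating the module's outputs while
learning equilibrates internally is what produces lasting behavioural
deficits.  λ is invariant to the gain (numerator and denominator both
scale as `g²`), as it should be: the lesion weakens signals, not the
volatility statistics.

## Parameters

| symbol | default | units | role |
|--------|---------|-------|------|
| ρ | 0.2 | — | TD discount on the non-primary reward term |
| μ | 0.1 | — | split of the boost between primary and TD terms |
| τ | 0.6 | value | softmax temperature, both policies |
| α | 0.3 | — | low-pass rate of the λ filter |
| β | 0.2 | — | learning-rate floor (λ ∈ [β, 1]) |
| ω | 0.15 | value/boost unit | boosting cost |

One fixed set for every simulation; no per-task tuning.  Values and
filter states initialise at zero with λ = β: the least-assumption start.

## Task environments and calibrated defaults

All environments are generated internally from the run seed; subject
`i` uses `base_seed + i`.

**Three-regime bandit (432 trials, three equal blocks, randomized
order).**  Two options with fixed magnitudes (1.0, 1.5).  `Stat`:
probabilities (0.7, 0.3).  `Stat2`: (0.6, 0.6) — maximal outcome noise
and no optimal choice.  `Vol`: the probability→option links permute
every 30 trials, first switch at a uniform random offset.  Magnitudes
are option properties and do not move; in every switch state the
higher-probability option has the higher expected value, so probability
is always the variable worth tracking.  The initial assignment gives the
larger magnitude to the rarer reward, which keeps the values close and
the discrimination hard.  Optimal-choice percentages are computed over
engaged (non-Stay) choices; the all-trials figure is reported alongside.

**Effort tasks (150 trials per phase).**  HR option: reward 1.0; LR
option: reward 0.4 (deterministic when chosen).  High effort costs 2.0,
low effort 0.2.  Variants: Effort (HR costly, LR cheap), NoEffort (both
cheap), DoubleEffort (both costly).  Protocols pre-train on NoEffort so
reward locations are known before the trade-off is introduced.  The
reward/cost numbers are calibrated defaults (all configurable), chosen
so that the intact agent's high-reward preference and the lesioned
agent's low-reward/disengagement shift both emerge at the fixed
parameter set.

**Conditioning chains (100 trials per stage, stage-wise).**  States are
cues indexed by distance from primary reward (magnitude 1.0, delivered
with certainty on the correct path).  Training starts with first-order
conditioning on the reward-adjacent cue and prepends one level per
stage up to third order.  Classical chains advance regardless of the
action; the instrumental maze advances only on the correct branch and
ends unrewarded otherwise.  Cue duration plays no role in a
trial-discrete model; each cue is one state-step.  The "cue-locked
dopamine response" is reported through its discrete proxy, the
non-primary term `g_DA · b (1−μ) ρ · g_dACC · max_a v(cue, ·)` at entry
to the cue state, averaged over the late-training window (last 25% of
final-stage trials — reported behaviour should be converged behaviour).

**Boost sweep.**  `b` clamped at 1..10, 40 runs each; per level the task
phase yields `performance` (mean reward signal as the possibly-lesioned
VTA transmits it, `g_DA · r · R`), `cost` (mean `ω b` on reward trials)
and `net value = performance − cost`.  A dopamine lesion attenuates the
reward component only — the boosting cost is charged undiminished —
which is why the lesioned net-value curve loses its interior optimum and
decreases monotonically.

## Statistical summaries

Cohort summaries are per-subject means; contrasts are paired t tests and
repeated-measures ANOVA (statsmodels), reported descriptively — test
statistics depend on the realized cohort and are not correctness
anchors.  Every summary is recomputable from the stored per-trial logs,
and outputs (CSV at 17 significant digits, JSON, manifest with SHA-256
checksums) are byte-stable under a fixed (config, seed).

## What the simulations do and do not show

The generator produces the study conditions themselves (schedules,
costs, chains); passing tests show the architecture reproduces the
qualitative phenomena — volatility-specific learning-rate increases
with noise-specific cortical activity, effort-sensitive boosting and its
lesion-induced collapse and compensation, recovery and apathy patterns,
and the classical/instrumental conditioning dissociation — under these
idealized conditions.  They do not show fits to any empirical dataset,
nor behaviour under reward structures other than the calibrated ones.

Known quantitative limits of the trial-discrete form, measured with this
package:

* **Near-reward maze accuracies.**  Choice probability is bounded by
  `softmax` at τ = 0.6 over values capped near `R + μb ≤ 2`, giving
  ≈85% at the reward-adjacent level — reference values near 98% for
  that level originate from continuous-time implementations whose
  effective selection is sharper.  The reward-furthest level (~71–73%)
  is reproduced.
* **Classical extinction depth.**  The per-order decay of the cue
  dopamine proxy is `(1−μ) ρ E[b] ≈ 0.65`, so third-order responses
  fall to ~40–65% of first-order rather than under 20%: the boost
  softmax over the converged `v_B = R − ωb` landscape cannot push
  `E[b]` below ≈3.6 at the fixed τ and ω.  The dissociation itself
  (geometric classical decay, sustained instrumental responses, higher
  instrumental boosting) is robust.
* **Volatile-block accuracy** depends on the switch period (a free
  design constant, default 30); across seeds it spans roughly 57–62%.
* The free-running boost *mean* is biased above the cost/benefit
  optimum because softmax sampling over the asymmetric 1..10 range has
  a heavy upper tail; the *modal* chosen level matches the clamped-sweep
  optimum within ±1 in every task × lesion combination.

Out of scope: intra-trial (continuous-time) dynamics, coupling to
external working-memory networks (the per-trial NE output is exposed but
unconsumed), and fitting to behavioural or neural data.
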