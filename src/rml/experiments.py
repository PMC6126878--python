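"""Protocol runners and cohort summaries.

Each runner simulates a cohort of independently seeded agents (subject
``i`` uses ``base_seed + i``), stores the complete per-step trial log,
and reduces it to the per-subject, per-condition summary statistics the
analyses need.  Summaries are always recomputable from the stored logs.

Conventions
-----------
* Effort tasks: action 0 = high-reward (HR), 1 = low-reward (LR),
  2 = Stay.  ``hr_pref`` is HR/(HR+LR) over engaged trials; ``stay_frac``
  is Stay over all trials.
* Conditioning: *order k* counts distance from primary reward, so the
  order-1 cue is adjacent to reward (trained first) and the order-3 cue
  is the episode's start cue at full depth (the "first choice" of a
  maze run).  The cue-locked dopamine response is reported through its
  discrete proxy: the non-primary (TD) term of the VTA signal evaluated
  at entry to the cue state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetaLearner, TrialRecord
from .params import DA_LESION, DACC_LESION, INTACT, LesionSpec, ModelParams
from .tasks import (
    BanditEnv,
    ChainEnv,
    ChainSpec,
    EffortEnv,
    EffortSpec,
    make_sim1_session,
)

__all__ = [
    "CohortResult",
    "LESION_BATTERY",
    "subject_rng",
    "run_simulation1",
    "run_simulation2a",
    "run_simulation2b",
    "run_simulation3",
    "boost_sweep",
    "summarize_cohort",
]

LESION_BATTERY: Mapping[str, LesionSpec] = {
    "intact": INTACT,
    "DA": DA_LESION,
    "dACC": DACC_LESION,
}

#: Fraction of trials at the end of a phase used for "late training" readouts.
LATE_WINDOW = 0.25


def subject_rng(base_seed: int, subject: int) -> np.random.Generator:
    """One seeded generator per simulated subject."""
    return np.random.default_rng((base_seed + subject) % 2**31)


@dataclass
class CohortResult:
    """Cohort output: per-subject summaries plus the full trial log."""

    summaries: pd.DataFrame
    trials: pd.DataFrame
    seeds: list[int]
    meta: dict = field(default_factory=dict)


def _record_rows(records: Iterable[TrialRecord], **extra) -> list[dict]:
    rows = []
    for rec in records:
        rows.append(
            dict(
                trial=rec.trial_index,
                step=rec.step_index,
                state=rec.state,
                boost=rec.boost,
                ne=rec.ne,
                action=rec.action,
                r=rec.outcome.r,
                R=rec.outcome.R,
                next_state=-1 if rec.outcome.next_state is None else rec.outcome.next_state,
                cost=rec.outcome.cost,
                da=rec.da,
                da_b=rec.da_b,
                pe_act=rec.pe_act,
                pe_boost=rec.pe_boost,
                lam_act=rec.lam_act,
                lam_boost=rec.lam_boost,
                state_max_v=rec.state_max_v,
                next_max_v=rec.next_max_v,
                **extra,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Simulation 1: learning-rate optimization in three statistical regimes
# ---------------------------------------------------------------------------


def run_simulation1(
    n_subjects: int = 12,
    seed: int = 0,
    n_trials: int = 432,
    params: ModelParams | None = None,
    lesion: LesionSpec | None = None,
) -> CohortResult:
    """Three-regime bandit session (equal blocks, randomized order).

    Per subject and regime the summary reports the mean learning rate of
    the action module, the mean unsigned prediction error (the dACC
    activity proxy), and — for the regimes that have an optimal choice —
    the fraction of trials on which the currently higher-expected-value
    arm was chosen ("Stay" scores as non-optimal).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or ModelParams()
    rows: list[dict] = []
    seeds = []
    for subj in range(n_subjects):
        rng = subject_rng(seed, subj)
        seeds.append((seed + subj) % 2**31)
        session = make_sim1_session(n_trials=n_trials, rng=rng)
        agent = MetaLearner(params=params, n_states=1, lesion=lesion, rng=rng)
        for spec in session:
            env = BanditEnv(spec)
            for _ in range(spec.n_trials):
                recs = agent.run_trial(env)
                high = env.high_arm()
                rows.extend(
                    _record_rows(
                        recs,
                        subject=subj,
                        regime=spec.regime,
                        block_trial=env.trial,
                        high_arm=-1 if high is None else high,
                        engaged=float(recs[0].action != 2),
                        optimal=np.nan if high is None else float(recs[0].action == high),
                    )
                )
    trials = pd.DataFrame(rows)
    engaged = trials[trials["engaged"] == 1.0]
    summ = (
        trials.groupby(["subject", "regime"])
        .agg(
            mean_lambda=("lam_act", "mean"),
            mean_abs_pe=("pe_act", lambda s: s.abs().mean()),
            accuracy_all=("optimal", "mean"),
            engaged_frac=("engaged", "mean"),
            mean_boost=("boost", "mean"),
            n_trials=("trial", "size"),
        )
        .reset_index()
        .merge(
            engaged.groupby(["subject", "regime"])["optimal"]
            .mean()
            .rename("accuracy")
            .reset_index(),
            on=["subject", "regime"],
            how="left",
        )
    )
    return CohortResult(summaries=summ, trials=trials, seeds=seeds, meta={"n_trials": n_trials})


# ---------------------------------------------------------------------------
# Simulations 2a/2b: effort-based decision-making and lesion batteries
# ---------------------------------------------------------------------------


def _run_effort_phases(
    agent: MetaLearner,
    phases: Sequence[tuple[str, EffortSpec]],
    subject: int,
) -> list[dict]:
    rows: list[dict] = []
    for phase_name, spec in phases:
        env = EffortEnv(spec)
        for _ in range(spec.n_trials):
            recs = agent.run_trial(env)
            rows.extend(
                _record_rows(recs, subject=subject, phase=phase_name, variant=spec.variant)
            )
    return rows


def _effort_metrics(phase_trials: pd.DataFrame) -> dict:
    hr = int((phase_trials["action"] == 0).sum())
    lr = int((phase_trials["action"] == 1).sum())
    stay = int((phase_trials["action"] == 2).sum())
    n = len(phase_trials)
    return dict(
        hr_pref=hr / (hr + lr) if hr + lr > 0 else np.nan,
        lr_frac=lr / n,
        stay_frac=stay / n,
        mean_boost=float(phase_trials["boost"].mean()),
    )


def run_simulation2a(
    n_subjects: int = 12,
    seed: int = 0,
    lesion_battery: Mapping[str, LesionSpec] = LESION_BATTERY,
    effort: EffortSpec | None = None,
    params: ModelParams | None = None,
) -> CohortResult:
    """Effort battery across lesion conditions.

    Every agent first learns the option rewards in a low-effort
    pre-training phase, then performs either the Effort or the NoEffort
    task.  Subject seeds are shared across conditions, so contrasts are
    paired.
    """
    params = params or ModelParams()
    base = effort or EffortSpec()
    task_specs = {
        "Effort": base.model_copy(update={"variant": "Effort"}),
        "NoEffort": base.model_copy(update={"variant": "NoEffort"}),
    }
    pretrain = base.model_copy(update={"variant": "NoEffort"})
    rows: list[dict] = []
    summ_rows: list[dict] = []
    seeds = []
    for lesion_name, lesion in lesion_battery.items():
        for task_name, task_spec in task_specs.items():
            for subj in range(n_subjects):
                rng = subject_rng(seed, subj)
                agent = MetaLearner(params=params, n_states=1, lesion=lesion, rng=rng)
                subj_rows = _run_effort_phases(
                    agent, [("pretrain", pretrain), ("task", task_spec)], subj
                )
                for row in subj_rows:
                    row.update(lesion=lesion_name, task=task_name)
                rows.extend(subj_rows)
                task_frame = pd.DataFrame(
                    [r for r in subj_rows if r["phase"] == "task"]
                )
                summ_rows.append(
                    dict(subject=subj, lesion=lesion_name, task=task_name)
                    | _effort_metrics(task_frame)
                )
        seeds = [(seed + s) % 2**31 for s in range(n_subjects)]
    return CohortResult(
        summaries=pd.DataFrame(summ_rows),
        trials=pd.DataFrame(rows),
        seeds=seeds,
        meta={"tasks": list(task_specs)},
    )


def run_simulation2b(
    n_subjects: int = 12,
    seed: int = 0,
    lesions: Mapping[str, LesionSpec] | None = None,
    effort: EffortSpec | None = None,
    params: ModelParams | None = None,
) -> CohortResult:
    """Recovery protocol: Effort phase, then NoEffort or DoubleEffort.

    The dopamine-lesioned agents are carried over from a completed
    Effort phase (pretrain -> Effort -> recovery task); an intact cohort
    runs the same sequences as control.  Summaries report the final
    (recovery) phase.
    """
    params = params or ModelParams()
    base = effort or EffortSpec()
    lesions = lesions or {"DA": DA_LESION, "intact": INTACT}
    recovery_tasks = ("NoEffort", "DoubleEffort")
    rows: list[dict] = []
    summ_rows: list[dict] = []
    for lesion_name, lesion in lesions.items():
        for task_name in recovery_tasks:
            for subj in range(n_subjects):
                rng = subject_rng(seed, subj)
                agent = MetaLearner(params=params, n_states=1, lesion=lesion, rng=rng)
                phases = [
                    ("pretrain", base.model_copy(update={"variant": "NoEffort"})),
                    ("effort", base.model_copy(update={"variant": "Effort"})),
                    ("recovery", base.model_copy(update={"variant": task_name})),
                ]
                subj_rows = _run_effort_phases(agent, phases, subj)
                for row in subj_rows:
                    row.update(lesion=lesion_name, task=task_name)
                rows.extend(subj_rows)
                rec_frame = pd.DataFrame([r for r in subj_rows if r["phase"] == "recovery"])
                summ_rows.append(
                    dict(subject=subj, lesion=lesion_name, task=task_name)
                    | _effort_metrics(rec_frame)
                )
    return CohortResult(
        summaries=pd.DataFrame(summ_rows),
        trials=pd.DataFrame(rows),
        seeds=[(seed + s) % 2**31 for s in range(n_subjects)],
        meta={"recovery_tasks": recovery_tasks},
    )


# ---------------------------------------------------------------------------
# Simulations 3a/3b: higher-order conditioning
# ---------------------------------------------------------------------------


def _cue_da_proxy(frame: pd.DataFrame, params: ModelParams, da_gain: float) -> pd.Series:
    """Non-primary VTA term at cue entry: ``gain*b*(1-mu)*rho*max_a v(s,.)``."""
    return da_gain * frame["boost"] * (1.0 - params.mu) * params.rho * frame["state_max_v"]


def run_simulation3(
    paradigm: str,
    n_subjects: int = 12,
    seed: int = 0,
    max_order: int = 3,
    n_trials_per_stage: int = 100,
    params: ModelParams | None = None,
    lesion: LesionSpec | None = None,
) -> CohortResult:
    """Stage-wise higher-order conditioning, classical or instrumental.

    Training proceeds stage by stage: first-order conditioning on the
    reward-adjacent cue, then each further stage prepends one cue (or
    choice) and starts the trial there.  Readouts come from the late
    window of the final stage: per-order cue-locked dopamine proxy,
    per-order choice accuracy (instrumental), and mean boosting level.
    """
    if paradigm not in ("classical", "instrumental"):
        raise ValueError(f"paradigm must be classical or instrumental, got {paradigm!r}")
    params = params or ModelParams()
    lesion = lesion or INTACT
    rows: list[dict] = []
    summ_rows: list[dict] = []
    for subj in range(n_subjects):
        rng = subject_rng(seed, subj)
        correct = tuple(int(a) for a in rng.integers(0, 2, size=max_order))
        agent = MetaLearner(params=params, n_states=max_order, lesion=lesion, rng=rng)
        subj_rows: list[dict] = []
        for stage in range(1, max_order + 1):
            spec = ChainSpec(
                paradigm=paradigm,
                depth=stage,
                max_order=max_order,
                correct_actions=correct,
                n_trials=n_trials_per_stage,
            )
            env = ChainEnv(spec)
            for _ in range(spec.n_trials):
                recs = agent.run_trial(env)
                subj_rows.extend(
                    _record_rows(
                        recs,
                        subject=subj,
                        paradigm=paradigm,
                        stage=stage,
                        stage_trial=env.trial,
                    )
                )
        for row in subj_rows:
            row["correct_action"] = correct[row["state"]]
        rows.extend(subj_rows)

        subj_frame = pd.DataFrame(subj_rows)
        final = subj_frame[subj_frame["stage"] == max_order]
        cutoff = n_trials_per_stage * (1.0 - LATE_WINDOW)
        late = final[final["stage_trial"] >= cutoff]
        summary = dict(subject=subj, paradigm=paradigm)
        summary["mean_boost"] = float(
            late.loc[late["step"] == 0, "boost"].mean()
        )
        proxy = _cue_da_proxy(late, params, lesion.da_gain)
        for order in range(1, max_order + 1):
            mask = late["state"] == order - 1
            summary[f"da_order{order}"] = float(proxy[mask].mean()) if mask.any() else np.nan
            if paradigm == "instrumental":
                sub = late[mask]
                summary[f"acc_order{order}"] = (
                    float((sub["action"] == sub["correct_action"]).mean())
                    if len(sub)
                    else np.nan
                )
        summ_rows.append(summary)
    return CohortResult(
        summaries=pd.DataFrame(summ_rows),
        trials=pd.DataFrame(rows),
        seeds=[(seed + s) % 2**31 for s in range(n_subjects)],
        meta={
            "paradigm": paradigm,
            "max_order": max_order,
            "n_trials_per_stage": n_trials_per_stage,
            "late_window": LATE_WINDOW,
        },
    )


# ---------------------------------------------------------------------------
# Clamped-boost cost/benefit sweep
# ---------------------------------------------------------------------------


def boost_sweep(
    variant: str = "Effort",
    lesion: LesionSpec | None = None,
    b_values: Sequence[int] = tuple(range(1, 11)),
    n_runs: int = 40,
    seed: int = 0,
    effort: EffortSpec | None = None,
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Cost/benefit curves under clamped boosting.

    For each clamped level ``b`` the agent runs the usual pretrain+task
    protocol with boost selection disabled.  Per ``b`` the sweep reports,
    over the task phase: ``performance`` — the mean reward signal as the
    (possibly lesioned) VTA transmits it, ``cost`` — the mean boosting
    cost charged on reward trials, and ``net_value = performance - cost``.
    """
    params = params or ModelParams()
    lesion = lesion or INTACT
    base = effort or EffortSpec()
    if any(b < 1 or b > params.n_boost_levels for b in b_values):
        raise ValueError(f"b_values must lie in 1..{params.n_boost_levels}")
    task_spec = base.model_copy(update={"variant": variant})
    pretrain = base.model_copy(update={"variant": "NoEffort"})
    out = []
    for b in b_values:
        perf, cost = [], []
        for run in range(n_runs):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed % 2**31, spawn_key=(b, run))
            )
            agent = MetaLearner(params=params, n_states=1, lesion=lesion, rng=rng, clamp_boost=b)
            reward_signal = []
            boost_cost = []
            for phase_name, spec in (("pretrain", pretrain), ("task", task_spec)):
                env = EffortEnv(spec)
                for _ in range(spec.n_trials):
                    recs = agent.run_trial(env)
                    if phase_name == "task":
                        o = recs[-1].outcome
                        reward_signal.append(lesion.da_gain * o.r * o.R)
                        boost_cost.append(o.r * params.omega * b)
            perf.append(np.mean(reward_signal))
            cost.append(np.mean(boost_cost))
        out.append(
            dict(
                b=b,
                performance=float(np.mean(perf)),
                cost=float(np.mean(cost)),
                net_value=float(np.mean(perf) - np.mean(cost)),
                performance_sem=float(stats.sem(perf)),
                net_value_sem=float(stats.sem(np.asarray(perf) - np.asarray(cost))),
                n_runs=n_runs,
            )
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------


def summarize_cohort(
    summaries: pd.DataFrame,
    value: str,
    condition: str,
    subject: str = "subject",
) -> dict:
    """Descriptive per-condition means, s.e.m. and paired contrasts.

    Requires every subject in every condition (paired design).  With a
    single subject the s.e.m. and test statistics are undefined and
    flagged as such rather than failing.  A repeated-measures F is
    added when more than two conditions are present.
    """
    pivot = summaries.pivot_table(index=subject, columns=condition, values=value)
    if pivot.isna().any().any():
        raise ValueError("mismatched subjects across conditions")
    n = len(pivot)
    result: dict = {
        "n_subjects": n,
        "means": pivot.mean().to_dict(),
        "sem": pivot.sem().to_dict() if n > 1 else {c: np.nan for c in pivot.columns},
        "sem_defined": n > 1,
        "contrasts": {},
    }
    conds = list(pivot.columns)
    if n > 1:
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                diff = pivot[a] - pivot[b]
                if np.allclose(diff, 0.0):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_rel(pivot[a], pivot[b])
                result["contrasts"][f"{a} vs {b}"] = {"t": float(t), "p": float(p)}
        if len(conds) > 2:
            try:
                from statsmodels.stats.anova import AnovaRM

                long = pivot.reset_index().melt(
                    id_vars=subject, var_name=condition, value_name=value
                )
                aov = AnovaRM(long, depvar=value, subject=subject, within=[condition]).fit()
                result["rm_anova"] = {
                    "F": float(aov.anova_table["F Value"].iloc[0]),
                    "p": float(aov.anova_table["Pr > F"].iloc[0]),
                }
            except Exception:  # degenerate data (e.g. zero variance): stay descriptive
                result["rm_anova"] = None
    return result
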