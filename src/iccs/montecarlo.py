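"""Monte-Carlo experiments over conditions.

Replicates the linear-vs-cubic comparison: the random benchmark policy
plays 1000 independent games under each probability curve and the per-trial
disaster probabilities are averaged into a trajectory per condition.  Per-rep
seeds derive deterministically from (base seed, condition label, rep index),
so conditions are comparable, reps independent, and the whole experiment is
reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Sequence

import numpy as np
import scipy.stats

from .model import GameLog, Policy, run_game
from .params import ModelParams
from .policies import RandomPolicy


@dataclasses.dataclass
class ExperimentSpec:
    """Conditions to simulate, how many reps, and with which policy."""

    conditions: list[tuple[str, ModelParams]]
    n_reps: int = 1000
    base_seed: int = 0
    policy: Policy = dataclasses.field(default_factory=RandomPolicy)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"condition labels must be unique, got {labels}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.base_seed < 0:
            raise ValueError(f"base_seed must be >= 0, got {self.base_seed}")


@dataclasses.dataclass
class TrajectorySummary:
    """Per-trial averages of one condition over all reps."""

    label: str
    n_reps: int
    mean_p: np.ndarray  # (T,) mean probability per trial
    ci_halfwidth: np.ndarray  # (T,) 95% CI half-width (t-based) per trial
    grand_mean_p: float
    occurrence_counts: np.ndarray  # (T,) disasters observed per trial over reps
    rep_grand_means: np.ndarray  # (n_reps,) per-rep mean p over trials
    p_matrix: np.ndarray  # (n_reps, T) raw per-trial probabilities


@dataclasses.dataclass
class ConditionComparison:
    """Ordering report between two conditions (a minus b)."""

    label_a: str
    label_b: str
    per_trial_diff: np.ndarray  # mean_p(a) - mean_p(b) per trial
    grand_mean_diff: float
    ci_low: float  # bootstrap 95% CI of the grand-mean difference
    ci_high: float
    a_exceeds_b_per_trial: np.ndarray  # bool flags, strict inequality


def rep_seed(base_seed: int, label: str, rep: int) -> np.random.SeedSequence:
    """Deterministic per-rep seed from (base seed, condition label, rep)."""
    return np.random.SeedSequence([base_seed, zlib.crc32(label.encode("utf-8")), rep])


def run_experiment(
    spec: ExperimentSpec, *, return_logs: bool = False
) -> dict[str, TrajectorySummary] | tuple[dict[str, TrajectorySummary], dict[str, list[GameLog]]]:
    """Run every condition for ``n_reps`` games and summarize trajectories."""
    summaries: dict[str, TrajectorySummary] = {}
    all_logs: dict[str, list[GameLog]] = {}
    for label, params in spec.conditions:
        p_rows = []
        occ_rows = []
        logs: list[GameLog] = []
        for rep in range(spec.n_reps):
            seed = rep_seed(spec.base_seed, label, rep)
            try:
                log = run_game(
                    spec.policy,
                    params,
                    seed,
                    condition=label,
                    seed_label=f"{spec.base_seed}/{label}/{rep}",
                )
            except ValueError as exc:
                raise type(exc)(f"condition {label!r}, rep {rep}: {exc}") from exc
            p_rows.append(log.table["p"].to_numpy())
            occ_rows.append(log.table["occurred"].to_numpy())
            if return_logs:
                logs.append(log)
        p_matrix = np.asarray(p_rows)
        n = p_matrix.shape[0]
        mean_p = p_matrix.mean(axis=0)
        if n > 1:
            tcrit = scipy.stats.t.ppf(0.975, n - 1)
            hw = tcrit * p_matrix.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            hw = np.zeros_like(mean_p)
        rep_grand = p_matrix.mean(axis=1)
        summaries[label] = TrajectorySummary(
            label=label,
            n_reps=n,
            mean_p=mean_p,
            ci_halfwidth=hw,
            grand_mean_p=float(rep_grand.mean()),
            occurrence_counts=np.asarray(occ_rows).sum(axis=0),
            rep_grand_means=rep_grand,
            p_matrix=p_matrix,
        )
        if return_logs:
            all_logs[label] = logs
    if return_logs:
        return summaries, all_logs
    return summaries


def compare_conditions(
    summary_a: TrajectorySummary,
    summary_b: TrajectorySummary,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> ConditionComparison:
    """Difference report a - b with a bootstrap 95% CI on the grand mean.

    The bootstrap resamples reps within each condition (percentile CI).
    Raises on mismatched trial counts.
    """
    if summary_a.mean_p.shape != summary_b.mean_p.shape:
        raise ValueError(
            f"trial counts differ: {summary_a.mean_p.shape[0]} vs "
            f"{summary_b.mean_p.shape[0]}"
        )
    per_trial = summary_a.mean_p - summary_b.mean_p
    grand = float(summary_a.rep_grand_means.mean() - summary_b.rep_grand_means.mean())
    rng = np.random.default_rng(seed)
    na, nb = len(summary_a.rep_grand_means), len(summary_b.rep_grand_means)
    idx_a = rng.integers(0, na, size=(n_boot, na))
    idx_b = rng.integers(0, nb, size=(n_boot, nb))
    boot = summary_a.rep_grand_means[idx_a].mean(axis=1) - summary_b.rep_grand_means[
        idx_b
    ].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ConditionComparison(
        label_a=summary_a.label,
        label_b=summary_b.label,
        per_trial_diff=per_trial,
        grand_mean_diff=grand,
        ci_low=float(lo),
        ci_high=float(hi),
        a_exceeds_b_per_trial=per_trial > 0,
    )


def linear_vs_cubic_spec(
    n_reps: int = 1000,
    base_seed: int = 0,
    policy: Policy | None = None,
    **param_changes,
) -> ExperimentSpec:
    """The benchmark experiment: random policy under k=1 and k=3."""
    return ExperimentSpec(
        conditions=[
            ("linear", ModelParams.linear(**param_changes)),
            ("cubic", ModelParams.cubic(**param_changes)),
        ],
        n_reps=n_reps,
        base_seed=base_seed,
        policy=policy if policy is not None else RandomPolicy(),
    )
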