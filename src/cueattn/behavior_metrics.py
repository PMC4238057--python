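"""Behavioral measures of attention and trial value, with their tests.

Hit rate and reaction time per (trial type, cue at the target location)
measure how strongly each cue attracts attention; false-alarm frequency
toward each cue location measures pre-target capture; abort frequency per
trial type tracks the overall reinforcement value of the trial (most
valuable R/N trials aborted least, least valuable P/N most).

Denominators: hit rate and reaction time use completed trials; false-alarm
and abort frequencies use all presented trials of the type, repeats
included (a repeated presentation is a new opportunity to break fixation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import CUE_ROLES, TRIAL_TYPES, TaskTimingParams
from .population_stats import proportions_differ
from .selectivity import rank_test_p
from .synthetic_session import truncated_exponential_cdf

__all__ = [
    "BehaviorSummary",
    "hit_rate",
    "reaction_time_stats",
    "false_alarm_freq",
    "abort_freq",
    "abort_contrasts",
    "chance_performance",
    "behavior_summary_table",
    "ChancePerformance",
]

#: Fig-6-style abort measurement windows, seconds after cue onset
ABORT_WINDOWS = {"cue": (0.0, 0.3), "delay": (0.3, 1.0)}


@dataclass(frozen=True)
class BehaviorSummary:
    metric: str
    trial_type: str
    condition: str  # cue role or abort window
    estimate: float
    se: float
    n: int


def _binomial_summary(metric, trial_type, condition, k, n) -> BehaviorSummary:
    if n == 0:
        return BehaviorSummary(metric, trial_type, condition, np.nan, np.nan, 0)
    p = k / n
    return BehaviorSummary(
        metric, trial_type, condition, p, float(np.sqrt(p * (1 - p) / n)), int(n)
    )


def _completed(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["outcome_label"].isin(
        ["hit", "miss_no_saccade", "miss_opposite", "miss_elsewhere"]
    )]


def _cue_at_target(trials: pd.DataFrame) -> np.ndarray:
    return np.where(
        trials["target_side"].to_numpy() == "contra",
        trials["cue_contra"].to_numpy(object),
        trials["cue_ipsi"].to_numpy(object),
    )


def hit_rate(trials: pd.DataFrame, trial_type: str, target_cue: str) -> BehaviorSummary:
    """Proportion of hits among completed trials of the type whose target
    appeared at the named cue's location, with binomial SE."""
    comp = _completed(trials)
    sel = comp[(comp["trial_type"] == trial_type) & (_cue_at_target(comp) == target_cue)]
    k = int((sel["outcome_label"] == "hit").sum())
    return _binomial_summary("hit_rate", trial_type, target_cue, k, len(sel))


def reaction_time_stats(
    trials: pd.DataFrame, trial_type: str, target_cue: str
) -> BehaviorSummary:
    """Mean and SE of saccade latency (saccade time - target onset) on hit
    trials of the condition, seconds."""
    comp = _completed(trials)
    sel = comp[
        (comp["trial_type"] == trial_type)
        & (_cue_at_target(comp) == target_cue)
        & (comp["outcome_label"] == "hit")
    ]
    n = len(sel)
    if n == 0:
        return BehaviorSummary("reaction_time", trial_type, target_cue, np.nan, np.nan, 0)
    rt = (sel["saccade_time"] - sel["target_onset"]).to_numpy(float)
    se = float(rt.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return BehaviorSummary("reaction_time", trial_type, target_cue, float(rt.mean()), se, n)


def _fa_cue_role(trials: pd.DataFrame) -> np.ndarray:
    """Cue role at the false-alarm endpoint ('' on non-FA trials)."""
    is_fa = (trials["outcome_label"] == "false_alarm").to_numpy()
    at_target = trials["saccade_endpoint_role"].to_numpy(object) == "target_loc"
    cue_t = _cue_at_target(trials)
    cue_o = np.where(
        trials["target_side"].to_numpy() == "contra",
        trials["cue_ipsi"].to_numpy(object),
        trials["cue_contra"].to_numpy(object),
    )
    role = np.where(at_target, cue_t, cue_o)
    return np.where(is_fa, role, "")


def false_alarm_freq(
    trials: pd.DataFrame, trial_type: str, cue_role: str
) -> BehaviorSummary:
    """Frequency of pre-target saccades to the named cue's location, over
    all presented trials of the type (repeats included)."""
    sel = trials[trials["trial_type"] == trial_type]
    k = int((_fa_cue_role(sel) == cue_role).sum())
    return _binomial_summary("false_alarm_freq", trial_type, cue_role, k, len(sel))


def abort_freq(
    trials: pd.DataFrame, trial_type: str, window: Optional[str] = None
) -> BehaviorSummary:
    """Frequency of aborts (fixation breaks away from both cue locations)
    among all presented trials of the type.

    ``window`` restricts to aborts whose saccade falls in the Fig-6-style
    'cue' (0-300 ms) or 'delay' (300-1000 ms) window after cue onset; None
    counts any pre-target abort.
    """
    if window is not None and window not in ABORT_WINDOWS:
        raise ValueError(f"window must be None or one of {sorted(ABORT_WINDOWS)}")
    sel = trials[trials["trial_type"] == trial_type]
    is_abort = (sel["outcome_label"] == "abort").to_numpy()
    if window is not None:
        lo, hi = ABORT_WINDOWS[window]
        t_rel = (sel["saccade_time"] - sel["cue_onset"]).to_numpy(float)
        with np.errstate(invalid="ignore"):
            is_abort = is_abort & (t_rel >= lo) & (t_rel < hi)
    return _binomial_summary(
        "abort_freq", trial_type, window or "all", int(is_abort.sum()), len(sel)
    )


def abort_contrasts(
    trials: pd.DataFrame,
    window: Optional[str] = None,
    contrasts: Sequence[tuple[str, str]] = (("R/P", "P/N"), ("R/P", "R/N"), ("R/N", "P/N")),
    bonferroni: int = 3,
) -> pd.DataFrame:
    """Pairwise chi-square comparisons of abort frequency between trial
    types, Bonferroni-corrected for the family of pairwise contrasts."""
    rows = []
    for t1, t2 in contrasts:
        s1 = abort_freq(trials, t1, window)
        s2 = abort_freq(trials, t2, window)
        p = proportions_differ(
            int(round(s1.estimate * s1.n)), s1.n, int(round(s2.estimate * s2.n)), s2.n
        )
        rows.append(
            {
                "contrast": f"{t1} vs {t2}",
                "window": window or "all",
                "p_raw": p,
                "p_corrected": min(1.0, p * bonferroni),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChancePerformance:
    probability: float          # best achievable hit rate with a blind saccade
    optimal_saccade_time: float  # s after cue onset
    capture_probability: float   # P(target onset falls in the captured span)


def chance_performance(
    timing: TaskTimingParams,
    target_onset_cdf: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    search_grid_s: float = 0.001,
) -> ChancePerformance:
    """Best hit probability for a blind strategy that saccades at a fixed
    time t on every trial.

    Such a saccade is a hit when the target happened to appear within
    [t - rt_max, t - rt_min] (so the saccade falls inside the response
    window) *and* the guessed side is correct (probability 1/2):

        p(t) = 0.5 * (F(t - rt_min) - F(t - rt_max))

    where F is the CDF of target onset relative to cue onset (by default the
    task's truncated shifted exponential measured from cue offset).  The
    maximum over t is found by grid search plus local refinement.
    """
    ms = 1e-3
    rt_lo, rt_hi = timing.rt_min * ms, timing.rt_max * ms
    if target_onset_cdf is None:
        t0 = timing.cue_duration * ms  # delay runs from cue offset
        lo = t0 + timing.target_delay_min * ms
        hi = t0 + timing.target_delay_max * ms

        def target_onset_cdf(x):
            return truncated_exponential_cdf(
                np.asarray(x, dtype=float), lo, hi,
                timing.target_delay_scale * ms,
            )

        support = (lo, hi)
    else:
        support = (0.0, 10.0)

    def p_hit(t):
        return 0.5 * (
            np.asarray(target_onset_cdf(t - rt_lo))
            - np.asarray(target_onset_cdf(t - rt_hi))
        )

    grid = np.arange(support[0] + rt_lo, support[1] + rt_hi + search_grid_s,
                     search_grid_s)
    vals = p_hit(grid)
    i = int(np.argmax(vals))
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, grid.size - 1)]
    if hi_b > lo_b:
        res = optimize.minimize_scalar(
            lambda t: -float(p_hit(t)), bounds=(lo_b, hi_b), method="bounded"
        )
        t_best, p_best = float(res.x), float(-res.fun)
        if p_best < vals[i]:
            t_best, p_best = float(grid[i]), float(vals[i])
    else:  # pragma: no cover - degenerate grid
        t_best, p_best = float(grid[i]), float(vals[i])
    return ChancePerformance(p_best, t_best, 2.0 * p_best)


def behavior_summary_table(trials: pd.DataFrame) -> pd.DataFrame:
    """All four metrics for every condition present in the trial table."""
    rows = []
    for tt in TRIAL_TYPES:
        if not (trials["trial_type"] == tt).any():
            continue
        for cue in CUE_ROLES[tt]:
            rows.append(hit_rate(trials, tt, cue))
            rows.append(reaction_time_stats(trials, tt, cue))
            rows.append(false_alarm_freq(trials, tt, cue))
        for window in (None, "cue", "delay"):
            rows.append(abort_freq(trials, tt, window))
    return pd.DataFrame([vars(r) for r in rows])


def rt_compare(
    trials: pd.DataFrame, trial_type: str, cue_a: str, cue_b: str
) -> float:
    """Unpaired rank-sum p comparing hit reaction times between two target
    cues of a trial type."""
    comp = _completed(trials)
    out = []
    for cue in (cue_a, cue_b):
        sel = comp[
            (comp["trial_type"] == trial_type)
            & (_cue_at_target(comp) == cue)
            & (comp["outcome_label"] == "hit")
        ]
        out.append((sel["saccade_time"] - sel["target_onset"]).to_numpy(float))
    return rank_test_p(out[0], out[1])
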