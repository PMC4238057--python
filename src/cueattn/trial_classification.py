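"""Assign each trial exactly one behavioral outcome label from raw events.

Rules, applied in order:

1. A gaze departure before target onset — or within 100 ms after it, too
   early to be a reaction to the target — is a *false alarm* if the saccade
   landed at one of the two cue locations, otherwise an *abort*.  Both are
   repeated trials and carry no reinforcement.
2. Otherwise the trial is *completed*: a saccade landing at the target
   location with latency within the response window is a *hit*; failing
   that, the trial is a *miss*, subtyped by whether no saccade occurred
   (or occurred too late), or the saccade went to the opposite cue location,
   or elsewhere.

Saccade endpoints arrive as discrete location roles (the angular-window
geometry is resolved by whatever produced the event table), so "at a cue
location" means endpoint role ``target_loc`` or ``opposite_cue_loc``.

Reinforcement follows the cue at the target location: reward on hits at the
R-cue location, punishment (air puff) on misses at the P-cue location,
nothing otherwise — never both on one trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic_session import Trial

__all__ = [
    "OutcomeLabel",
    "COMPLETED_LABELS",
    "classify_trial",
    "classify_trials",
    "derive_reinforcement",
]

COMPLETED_LABELS = frozenset(
    {"hit", "miss_no_saccade", "miss_opposite", "miss_elsewhere"}
)
ALL_LABELS = COMPLETED_LABELS | {"false_alarm", "abort"}

#: saccades within this many seconds of target onset cannot be reactions to it
EARLY_SACCADE_S = 0.100
#: response window relative to target onset, seconds
RT_WINDOW_S = (0.100, 0.600)

_CUE_ROLES_AT_LOCATIONS = ("target_loc", "opposite_cue_loc")


@dataclass(frozen=True)
class OutcomeLabel:
    value: str

    def __post_init__(self) -> None:
        if self.value not in ALL_LABELS:
            raise ValueError(f"unknown outcome label {self.value!r}")

    @property
    def completed(self) -> bool:
        return self.value in COMPLETED_LABELS


def _get(trial, name):
    if isinstance(trial, Trial):
        return getattr(trial, name)
    v = trial[name]
    return None if pd.isna(v) else v


def classify_trial(trial: Trial | Mapping | pd.Series) -> OutcomeLabel:
    """Classify one trial from its raw events.  Exactly one label results."""
    sacc = _get(trial, "saccade_time")
    target = _get(trial, "target_onset")
    fix = _get(trial, "fixation_onset")
    endpoint = _get(trial, "saccade_endpoint_role")

    if sacc is not None and fix is not None and sacc < fix:
        raise ValueError("malformed trial: saccade precedes fixation onset")
    if target is None and sacc is None:
        raise ValueError("malformed trial: no target onset and no fixation break")

    # fixation break: pre-target, or too soon after the target to be a reaction
    if sacc is not None and (target is None or sacc <= target + EARLY_SACCADE_S):
        if endpoint in _CUE_ROLES_AT_LOCATIONS:
            return OutcomeLabel("false_alarm")
        return OutcomeLabel("abort")

    if sacc is None:
        return OutcomeLabel("miss_no_saccade")
    latency = sacc - target
    if latency > RT_WINDOW_S[1]:
        # no saccade within the response window
        return OutcomeLabel("miss_no_saccade")
    if endpoint == "target_loc":
        return OutcomeLabel("hit")
    if endpoint == "opposite_cue_loc":
        return OutcomeLabel("miss_opposite")
    return OutcomeLabel("miss_elsewhere")


def derive_reinforcement(trial: Trial | Mapping | pd.Series, label: OutcomeLabel) -> str:
    """Outcome delivered on a completed trial: 'reward', 'punishment', 'none'."""
    if not label.completed:
        raise ValueError("reinforcement is defined only for completed trials")
    side = _get(trial, "target_side")
    cue_at_target = _get(trial, "cue_contra" if side == "contra" else "cue_ipsi")
    if label.value == "hit" and cue_at_target == "R":
        return "reward"
    if label.value != "hit" and cue_at_target == "P":
        return "punishment"
    return "none"


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a trial table.

    Returns a copy with ``outcome_label``, ``completed`` and
    ``reinforcement`` columns added ('' reinforcement on break trials).
    """
    df = trials.copy()
    sacc = df["saccade_time"].to_numpy(float)
    target = df["target_onset"].to_numpy(float)
    fix = df["fixation_onset"].to_numpy(float)
    endpoint = df["saccade_endpoint_role"].astype(object).to_numpy()

    has_sacc = ~np.isnan(sacc)
    has_target = ~np.isnan(target)
    if np.any(has_sacc & ~np.isnan(fix) & (sacc < fix)):
        raise ValueError("malformed trial: saccade precedes fixation onset")
    if np.any(~has_target & ~has_sacc):
        raise ValueError("malformed trial: no target onset and no fixation break")

    at_cue = np.isin(endpoint.astype(str), _CUE_ROLES_AT_LOCATIONS)
    is_break = has_sacc & (~has_target | (sacc <= target + EARLY_SACCADE_S))
    latency = sacc - target
    in_window = has_sacc & ~is_break & (latency <= RT_WINDOW_S[1])

    label = np.full(len(df), "miss_no_saccade", dtype=object)
    label[is_break & at_cue] = "false_alarm"
    label[is_break & ~at_cue] = "abort"
    hit = in_window & (endpoint == "target_loc")
    label[hit] = "hit"
    label[in_window & (endpoint == "opposite_cue_loc")] = "miss_opposite"
    label[in_window & (endpoint == "elsewhere")] = "miss_elsewhere"

    completed = ~is_break
    cue_at_target = np.where(
        df["target_side"].to_numpy() == "contra",
        df["cue_contra"].to_numpy(object),
        df["cue_ipsi"].to_numpy(object),
    )
    reinf = np.full(len(df), "", dtype=object)
    reinf[completed] = "none"
    reinf[completed & hit & (cue_at_target == "R")] = "reward"
    reinf[completed & ~hit & (cue_at_target == "P")] = "punishment"

    df["outcome_label"] = label
    df["completed"] = completed
    df["reinforcement"] = reinf
    return df
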