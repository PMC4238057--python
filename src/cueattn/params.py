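"""Parameter containers for the detection-task session generator.

The task: after a variable fixation period, two conditioned cues (one per
hemifield) appear for 300 ms; following a variable delay a barely-perceptible
target flashes at one cue location and the subject must saccade to it within a
100-600 ms response window.  Cues signal reward (R), punishment (P), or
nothing (N), giving three interleaved trial types (R/P, R/N, P/N).

Default behavioral calibrations (hit rates, reaction times, false-alarm and
abort frequencies) are the published session-pooled values for this task, so a
default-parameterized synthetic session reproduces the printed behavior when
re-analyzed from raw events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

__all__ = [
    "TRIAL_TYPES",
    "CUE_ROLES",
    "TaskTimingParams",
    "BehaviorParams",
    "NeuronParams",
    "MONKEY_L_ABORT_TOTALS",
    "MONKEY_O_ABORT_TOTALS",
]

#: the three randomly interleaved trial types
TRIAL_TYPES: Tuple[str, ...] = ("R/P", "R/N", "P/N")

#: cue roles present on each trial type, (primary, secondary)
CUE_ROLES: Mapping[str, Tuple[str, str]] = {
    "R/P": ("R", "P"),
    "R/N": ("R", "N"),
    "P/N": ("P", "N"),
}


@dataclass(frozen=True)
class TaskTimingParams:
    """Trial timing constants, in milliseconds unless noted.

    Fixation and target delays are shifted exponentials truncated to
    [min, max] (scale = mean of the unshifted exponential part); the target
    delay is measured from cue offset, so the earliest target onset is
    700 ms after cue onset.
    """

    fixation_min: float = 500.0
    fixation_max: float = 1500.0
    fixation_scale: float = 170.0
    cue_duration: float = 300.0
    target_delay_min: float = 400.0
    target_delay_max: float = 4000.0
    target_delay_scale: float = 390.0
    target_duration: float = 50.0
    rt_min: float = 100.0   # response window relative to target onset
    rt_max: float = 600.0

    def __post_init__(self) -> None:
        for name in (
            "fixation_min",
            "fixation_max",
            "fixation_scale",
            "cue_duration",
            "target_delay_min",
            "target_delay_max",
            "target_delay_scale",
            "target_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.fixation_min < self.fixation_max:
            raise ValueError("fixation_min must be < fixation_max")
        if not self.target_delay_min < self.target_delay_max:
            raise ValueError("target_delay_min must be < target_delay_max")
        if not 0 <= self.rt_min < self.rt_max:
            raise ValueError("rt window must satisfy 0 <= rt_min < rt_max")


# Fig-2-calibrated behavioral defaults, keyed (trial_type, cue at target /
# cue saccaded to).  Proportions; reaction times in seconds.
DEFAULT_HIT_RATE: Mapping[Tuple[str, str], float] = {
    ("R/P", "R"): 0.879,
    ("R/P", "P"): 0.362,
    ("R/N", "R"): 0.896,
    ("R/N", "N"): 0.288,
    ("P/N", "P"): 0.744,
    ("P/N", "N"): 0.597,
}

DEFAULT_RT_MEAN: Mapping[Tuple[str, str], float] = {
    ("R/P", "R"): 0.189,
    ("R/P", "P"): 0.266,
    ("R/N", "R"): 0.187,
    ("R/N", "N"): 0.277,
    ("P/N", "P"): 0.222,
    ("P/N", "N"): 0.247,
}

DEFAULT_FALSE_ALARM_RATE: Mapping[Tuple[str, str], float] = {
    ("R/P", "R"): 0.333,
    ("R/P", "P"): 0.034,
    ("R/N", "R"): 0.353,
    ("R/N", "N"): 0.023,
    ("P/N", "P"): 0.147,
    ("P/N", "N"): 0.097,
}

#: per-trial-type abort (fixation-break-away-from-cues) totals per subject
MONKEY_L_ABORT_TOTALS: Mapping[str, float] = {"R/P": 0.082, "R/N": 0.069, "P/N": 0.127}
MONKEY_O_ABORT_TOTALS: Mapping[str, float] = {"R/P": 0.012, "R/N": 0.009, "P/N": 0.028}


def _split_abort_totals(
    totals: Mapping[str, float], cue_fraction: float = 0.25
) -> Mapping[Tuple[str, str], float]:
    """Split per-trial-type abort totals between the cue (0-300 ms) and delay
    (300 ms - target onset) windows.  Only the per-type totals are published;
    the window split is a generator convention."""
    out = {}
    for tt, p in totals.items():
        out[(tt, "cue")] = cue_fraction * p
        out[(tt, "delay")] = (1.0 - cue_fraction) * p
    return out


@dataclass(frozen=True)
class BehaviorParams:
    """Per-condition behavioral outcome probabilities.

    hit_rate / rt_mean are keyed by (trial_type, cue role at the target
    location); false_alarm_rate by (trial_type, cue role saccaded to);
    abort_rate by (trial_type, window) with window in {"cue", "delay"}.
    All probabilities are per presented trial (repeats count as trials).
    """

    hit_rate: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_HIT_RATE)
    )
    rt_mean: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RT_MEAN)
    )
    rt_sd: float = 0.050
    false_alarm_rate: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FALSE_ALARM_RATE)
    )
    abort_rate: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: _split_abort_totals(MONKEY_L_ABORT_TOTALS)
    )
    # miss subtype proportions: (no saccade, opposite cue location, elsewhere)
    miss_split: Tuple[float, float, float] = (0.61, 0.28, 0.11)

    def __post_init__(self) -> None:
        for m in (self.hit_rate, self.false_alarm_rate, self.abort_rate):
            for k, v in m.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability {k} = {v} outside [0, 1]")
        if self.rt_sd <= 0:
            raise ValueError("rt_sd must be > 0")
        if abs(sum(self.miss_split) - 1.0) > 1e-9 or min(self.miss_split) < 0:
            raise ValueError("miss_split must be a probability vector")
        # a trial has at most one fixation break: the break categories must
        # leave room for a completed trial
        for tt in TRIAL_TYPES:
            roles = CUE_ROLES[tt]
            total = (
                sum(self.false_alarm_rate.get((tt, r), 0.0) for r in roles)
                + self.abort_rate.get((tt, "cue"), 0.0)
                + self.abort_rate.get((tt, "delay"), 0.0)
            )
            if total >= 1.0:
                raise ValueError(
                    f"fixation-break probabilities on {tt} trials sum to {total} >= 1"
                )

    @classmethod
    def monkey_L(cls, cue_fraction: float = 0.25) -> "BehaviorParams":
        return cls(abort_rate=_split_abort_totals(MONKEY_L_ABORT_TOTALS, cue_fraction))

    @classmethod
    def monkey_O(cls, cue_fraction: float = 0.75) -> "BehaviorParams":
        # monkey O expressed the value-dependent abort pattern around cue time
        return cls(abort_rate=_split_abort_totals(MONKEY_O_ABORT_TOTALS, cue_fraction))

    def with_abort_totals(
        self, totals: Mapping[str, float], cue_fraction: float = 0.25
    ) -> "BehaviorParams":
        return replace(self, abort_rate=_split_abort_totals(totals, cue_fraction))


@dataclass(frozen=True)
class NeuronParams:
    """Log-linear rate model for one synthetic unit.

    Epoch rate = baseline_rate[epoch] * exp(sum of active betas), with betas
    activated by reward presence, reward-cue laterality, punishment-cue
    laterality (primary and secondary), and abort propensity.
    """

    unit_id: str
    unit_kind: str = "SUA"  # or "MUA"
    baseline_rate: Tuple[float, float, float] = (10.0, 10.0, 10.0)
    beta_reward_present: float = 0.0
    beta_reward_contra: float = 0.0
    beta_punish_contra: float = 0.0
    beta_punish_secondary_contra: float = 0.0
    beta_abort: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_kind not in ("SUA", "MUA"):
            raise ValueError("unit_kind must be 'SUA' or 'MUA'")
        if len(self.baseline_rate) != 3 or min(self.baseline_rate) <= 0:
            raise ValueError("baseline_rate must be three positive rates")
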