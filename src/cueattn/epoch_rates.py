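"""Per-trial, per-epoch firing rates with inclusion and truncation rules.

Firing rates are measured in three 300-ms half-open windows after cue onset,
E1 = [100, 400) ms, E2 = [400, 700) ms, E3 = [700, 1000) ms, covering the
cue-driven response, the pre-target delay, and the delay during which the
target can appear.

Inclusion rules:

* On completed trials, an epoch is excluded if the target appeared before
  the end of the window (``excluded_target_intrusion``), since target- and
  saccade-driven activity would contaminate the rate.
* On fixation-break trials, the window is truncated at the break; the epoch
  is excluded if the break occurred less than 100 ms after the window start
  (``excluded_short_abort``), and the rate otherwise uses the effective
  (truncated) duration.

Multi-unit timestamp trains recorded on the same channel as a sorted single
unit are cleaned by removing MUA timestamps within 2 ms of any SUA
timestamp, so threshold double-crossings of the isolated unit do not
contaminate the multi-unit signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic_session import SpikeTrain, Trial

__all__ = [
    "EPOCHS",
    "EPOCH_NAMES",
    "EpochRate",
    "mua_dedup",
    "epoch_rate",
    "rates_table",
]

#: analysis epochs, seconds after cue onset, half-open [start, end)
EPOCHS: Mapping[str, tuple[float, float]] = {
    "E1": (0.1, 0.4),
    "E2": (0.4, 0.7),
    "E3": (0.7, 1.0),
}
EPOCH_NAMES = tuple(EPOCHS)

#: a break must leave at least this much of a window to yield a rate
MIN_TRUNCATED_S = 0.100

STATUS_INCLUDED = "included"
STATUS_TARGET = "excluded_target_intrusion"
STATUS_SHORT = "excluded_short_abort"


@dataclass(frozen=True)
class EpochRate:
    unit_id: str
    trial_id: int
    epoch: str
    rate: float  # spikes/s, nan when excluded
    effective_duration: float  # s, nan when excluded
    status: str


def mua_dedup(
    mua_timestamps: np.ndarray,
    sua_timestamp_sets: Iterable[np.ndarray],
    window: float = 0.002,
) -> np.ndarray:
    """Remove MUA timestamps within ``window`` of any SUA timestamp.

    Keeps MUA timestamps t with |t - s| > window for every SUA timestamp s
    (strict: a timestamp exactly at the window edge is removed).  Inputs must
    be sorted; units of ``window`` match the timestamps.  Order preserved.
    """
    mua = np.asarray(mua_timestamps, dtype=float)
    suas = [np.asarray(s, dtype=float) for s in sua_timestamp_sets]
    for arr in [mua, *suas]:
        if arr.size and np.any(np.diff(arr) < 0):
            raise ValueError("timestamps must be sorted")
    if not suas or all(s.size == 0 for s in suas):
        return mua.copy()
    sua = np.sort(np.concatenate([s for s in suas if s.size]))
    idx = np.searchsorted(sua, mua)
    left = np.where(idx > 0, mua - sua[np.clip(idx - 1, 0, sua.size - 1)], np.inf)
    right = np.where(idx < sua.size, sua[np.clip(idx, 0, sua.size - 1)] - mua, np.inf)
    nearest = np.minimum(np.abs(left), np.abs(right))
    return mua[nearest > window]


def epoch_rate(
    spikes: np.ndarray,
    trial: Trial | pd.Series | Mapping,
    epoch: str,
    abort_time: Optional[float] = None,
) -> EpochRate:
    """Rate of one unit in one epoch of one trial.

    ``spikes`` are timestamps aligned to cue onset (seconds); ``abort_time``
    is the fixation-break time aligned to cue onset, or None on completed
    trials, in which case the target-intrusion rule applies.
    """
    if epoch not in EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}")
    start, end = EPOCHS[epoch]

    def g(name, default=None):
        if isinstance(trial, Trial):
            v = getattr(trial, name, default)
        else:
            v = trial[name] if name in trial else default
        return None if v is None or (np.isscalar(v) and pd.isna(v)) else v

    unit_id = str(g("unit_id", "") or "")
    trial_id = int(g("trial_id", 0) or 0)

    if abort_time is not None:
        if abort_time < start + MIN_TRUNCATED_S:
            return EpochRate(unit_id, trial_id, epoch, np.nan, np.nan, STATUS_SHORT)
        eff_end = min(end, abort_time)
    else:
        target = g("target_onset")
        cue = g("cue_onset")
        if target is not None:
            target_rel = target - (cue or 0.0)
            if target_rel < end:
                return EpochRate(unit_id, trial_id, epoch, np.nan, np.nan, STATUS_TARGET)
        eff_end = end

    ts = np.asarray(spikes, dtype=float)
    count = int(np.searchsorted(ts, eff_end) - np.searchsorted(ts, start))
    dur = eff_end - start
    return EpochRate(unit_id, trial_id, epoch, count / dur, dur, STATUS_INCLUDED)


def rates_table(
    trials: pd.DataFrame,
    spikes: Mapping[str, SpikeTrain] | Sequence[SpikeTrain],
    epochs: Sequence[str] = EPOCH_NAMES,
) -> pd.DataFrame:
    """Per (unit, trial, epoch) rates for a classified trial table.

    Requires an ``outcome_label`` column (see trial_classification).  Break
    trials (false alarms as well as aborts) are truncated at the saccade;
    completed trials follow the target-intrusion rule.  Returns a DataFrame
    with columns unit_id, unit_kind, trial_id, epoch, rate,
    effective_duration, status.
    """
    if "outcome_label" not in trials:
        raise ValueError("trials must be classified first (outcome_label missing)")
    for e in epochs:
        if e not in EPOCHS:
            raise ValueError(f"unknown epoch {e!r}")
    if not isinstance(spikes, Mapping):
        spikes = {st.unit_id: st for st in spikes}

    cue = trials["cue_onset"].to_numpy(float)
    target_rel = trials["target_onset"].to_numpy(float) - cue
    sacc_rel = trials["saccade_time"].to_numpy(float) - cue
    is_break = trials["outcome_label"].isin(["false_alarm", "abort"]).to_numpy()
    trial_ids = trials["trial_id"].to_numpy()
    n = len(trials)

    frames = []
    for st in spikes.values():
        ts = st.timestamps
        for e in epochs:
            start, end = EPOCHS[e]
            eff_end = np.where(
                is_break, np.minimum(end, sacc_rel), np.full(n, end)
            )
            status = np.full(n, STATUS_INCLUDED, dtype=object)
            status[~is_break & (target_rel < end)] = STATUS_TARGET
            status[is_break & (sacc_rel < start + MIN_TRUNCATED_S)] = STATUS_SHORT
            ok = status == STATUS_INCLUDED

            lo = np.searchsorted(ts, cue + start)
            hi = np.searchsorted(ts, cue + eff_end)
            dur = np.where(ok, eff_end - start, np.nan)
            rate = np.where(ok, (hi - lo) / dur, np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": st.unit_id,
                        "unit_kind": st.unit_kind,
                        "trial_id": trial_ids,
                        "epoch": e,
                        "rate": rate,
                        "effective_duration": dur,
                        "status": status,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "unit_id",
                "unit_kind",
                "trial_id",
                "epoch",
                "rate",
                "effective_duration",
                "status",
            ]
        )
    return pd.concat(frames, ignore_index=True)
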