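"""Synthetic detection-task sessions: trial events, outcomes, spike trains.

The generator emits a complete session — a trial event table plus per-unit
spike timestamp trains — with the statistical structure the downstream
analysis assumes:

* trial timing follows the task's truncated shifted-exponential fixation and
  target delays (target delay measured from cue offset);
* behavioral outcomes (hit/miss, false alarms toward either cue, aborts in
  the cue or delay window) are drawn from per-condition probabilities whose
  defaults are the published session-pooled values, and broken trials are
  re-queued with re-randomized configuration;
* spike trains are piecewise-constant inhomogeneous Poisson within the three
  analysis epochs after cue onset, with epoch rates log-linearly modulated by
  reward presence, reward/punishment-cue laterality, and abort propensity.

The generator records its intended outcome per trial (``gen_outcome``) so the
event-based classifier can be validated against it; all analysis stages work
from the raw event columns only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    CUE_ROLES,
    TRIAL_TYPES,
    BehaviorParams,
    NeuronParams,
    TaskTimingParams,
)

__all__ = [
    "Trial",
    "SpikeTrain",
    "SessionData",
    "draw_delay",
    "generate_trial",
    "generate_spikes",
    "generate_session",
    "sample_population",
    "write_session",
    "read_session",
]

# analysis epochs relative to cue onset, seconds, half-open [start, end)
EPOCH_WINDOWS_S: Tuple[Tuple[float, float], ...] = ((0.1, 0.4), (0.4, 0.7), (0.7, 1.0))

#: columns of the trial event table, in file order
TRIAL_COLUMNS = [
    "trial_id",
    "trial_type",
    "cue_contra",
    "cue_ipsi",
    "cue_set",
    "fixation_onset",
    "cue_onset",
    "cue_offset",
    "target_onset",
    "target_side",
    "saccade_time",
    "saccade_endpoint_role",
    "gen_outcome",
    "repeated_from",
]


@dataclass
class Trial:
    """One trial's cue configuration and event times (seconds)."""

    trial_id: int
    trial_type: str
    cue_contra: str
    cue_ipsi: str
    cue_set: int
    fixation_onset: float
    cue_onset: float
    cue_offset: float
    target_onset: Optional[float]  # None on pre-target fixation breaks
    target_side: str  # "contra" or "ipsi" (scheduled side on break trials)
    saccade_time: Optional[float]
    saccade_endpoint_role: Optional[str]  # target_loc / opposite_cue_loc / elsewhere
    gen_outcome: Optional[str] = None
    outcome_label: Optional[str] = None
    repeated_from: Optional[int] = None


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds, session clock) for one unit."""

    unit_id: str
    unit_kind: str
    timestamps: np.ndarray
    valid_interval: Tuple[float, float]

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be sorted")
        self.timestamps = ts


@dataclass
class SessionData:
    trials: pd.DataFrame
    spikes: Dict[str, SpikeTrain]
    meta: dict = field(default_factory=dict)


def draw_delay(
    min_ms: float,
    max_ms: float,
    scale_ms: float,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> np.ndarray | float:
    """Draw from a shifted exponential truncated to [min_ms, max_ms].

    The draw is min + Exp(scale), resampled until it falls at or below max
    (truncation by rejection), so the density is proportional to
    exp(-(x - min)/scale) on [min, max] with its mode at min.
    """
    if scale_ms <= 0:
        raise ValueError("scale must be > 0")
    if not min_ms < max_ms:
        raise ValueError("min must be < max")
    n = 1 if size is None else int(size)
    out = min_ms + rng.exponential(scale_ms, n)
    bad = out > max_ms
    while bad.any():
        out[bad] = min_ms + rng.exponential(scale_ms, int(bad.sum()))
        bad = out > max_ms
    if size is None:
        return float(out[0])
    return out


def truncated_exponential_cdf(
    x: np.ndarray | float, min_v: float, max_v: float, scale: float
) -> np.ndarray | float:
    """CDF of the shifted, truncated exponential used for task delays."""
    x = np.asarray(x, dtype=float)
    z = np.clip(x - min_v, 0.0, max_v - min_v)
    denom = 1.0 - np.exp(-(max_v - min_v) / scale)
    out = (1.0 - np.exp(-z / scale)) / denom
    return out if out.ndim else float(out)


_RT_LOC_CACHE: Dict[Tuple[float, float, float, float], float] = {}


def _rt_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a normal truncated to [lo, hi] whose truncated mean equals
    ``target_mean`` — so generated reaction times average to the calibrated
    value despite the response-window truncation."""
    key = (target_mean, sd, lo, hi)
    if key not in _RT_LOC_CACHE:
        if not lo < target_mean < hi:
            raise ValueError("rt mean must lie inside the response window")

        def trunc_mean(loc: float) -> float:
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

        from scipy.optimize import brentq

        _RT_LOC_CACHE[key] = float(
            brentq(lambda m: trunc_mean(m) - target_mean, lo - 5 * sd, hi + 5 * sd)
        )
    return _RT_LOC_CACHE[key]


def _per_type_break_probs(behavior: BehaviorParams) -> Dict[str, np.ndarray]:
    """Cumulative probabilities of the mutually exclusive fixation-break
    categories per trial type: [FA->primary cue, FA->secondary cue,
    abort in cue window, abort in delay window]."""
    out = {}
    for tt in TRIAL_TYPES:
        r1, r2 = CUE_ROLES[tt]
        p = np.array(
            [
                behavior.false_alarm_rate.get((tt, r1), 0.0),
                behavior.false_alarm_rate.get((tt, r2), 0.0),
                behavior.abort_rate.get((tt, "cue"), 0.0),
                behavior.abort_rate.get((tt, "delay"), 0.0),
            ]
        )
        out[tt] = np.cumsum(p)
    return out


def _draw_trial_batch(
    timing: TaskTimingParams,
    behavior: BehaviorParams,
    trial_types: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized draw of n independent trials (times relative to trial start).

    Pre-target fixation-break events are drawn first; surviving trials get a
    hit/miss outcome conditional on the cue at the scheduled target location.
    """
    n = len(trial_types)
    tt = np.asarray(trial_types, dtype=object)

    primary = np.array([CUE_ROLES[t][0] for t in tt], dtype=object)
    secondary = np.array([CUE_ROLES[t][1] for t in tt], dtype=object)
    flip = rng.integers(0, 2, n).astype(bool)  # which cue is contralateral
    cue_contra = np.where(flip, primary, secondary)
    cue_ipsi = np.where(flip, secondary, primary)
    cue_set = rng.integers(1, 3, n)
    target_contra = rng.integers(0, 2, n).astype(bool)
    target_side = np.where(target_contra, "contra", "ipsi")
    cue_at_target = np.where(target_contra, cue_contra, cue_ipsi)

    ms = 1e-3
    fix_dur = draw_delay(
        timing.fixation_min, timing.fixation_max, timing.fixation_scale, rng, n
    ) * ms
    delay = draw_delay(
        timing.target_delay_min,
        timing.target_delay_max,
        timing.target_delay_scale,
        rng,
        n,
    ) * ms
    fixation_onset = np.zeros(n)
    cue_onset = fix_dur
    cue_offset = cue_onset + timing.cue_duration * ms
    sched_target = cue_offset + delay

    # --- fixation breaks (at most one per trial) -------------------------
    cum = _per_type_break_probs(behavior)
    cum_rows = np.vstack([cum[t] for t in tt])
    u = rng.random(n)
    cat = (u[:, None] >= cum_rows).sum(axis=1)  # 0..3 break category, 4 = none
    is_fa1 = cat == 0
    is_fa2 = cat == 1
    is_ab_cue = cat == 2
    is_ab_delay = cat == 3
    is_break = cat < 4

    saccade_time = np.full(n, np.nan)
    endpoint = np.full(n, None, dtype=object)
    gen_outcome = np.full(n, None, dtype=object)

    # false alarms: saccade to a cue location, uniform over the pre-target span
    for mask, role in ((is_fa1, primary), (is_fa2, secondary)):
        if mask.any():
            t0 = cue_onset[mask]
            saccade_time[mask] = t0 + rng.random(mask.sum()) * (sched_target[mask] - t0)
            fa_side_contra = cue_contra[mask] == role[mask]
            at_target = fa_side_contra == target_contra[mask]
            endpoint[mask] = np.where(at_target, "target_loc", "opposite_cue_loc")
            gen_outcome[mask] = "false_alarm"
    # aborts: saccade away from both cue locations
    if is_ab_cue.any():
        m = is_ab_cue
        saccade_time[m] = cue_onset[m] + rng.random(m.sum()) * (timing.cue_duration * ms)
        endpoint[m] = "elsewhere"
        gen_outcome[m] = "abort"
    if is_ab_delay.any():
        m = is_ab_delay
        t0 = cue_onset[m] + timing.cue_duration * ms
        saccade_time[m] = t0 + rng.random(m.sum()) * (sched_target[m] - t0)
        endpoint[m] = "elsewhere"
        gen_outcome[m] = "abort"

    # --- completed trials: hit vs miss ----------------------------------
    comp = ~is_break
    p_hit = np.array(
        [behavior.hit_rate[(t, c)] for t, c in zip(tt, cue_at_target)], dtype=float
    )
    is_hit = comp & (rng.random(n) < p_hit)
    is_miss = comp & ~is_hit

    rt_lo, rt_hi = timing.rt_min * ms, timing.rt_max * ms
    if is_hit.any():
        mu = np.array(
            [
                _rt_loc(behavior.rt_mean[(t, c)], behavior.rt_sd, rt_lo, rt_hi)
                for t, c in zip(tt[is_hit], cue_at_target[is_hit])
            ]
        )
        a = (rt_lo - mu) / behavior.rt_sd
        b = (rt_hi - mu) / behavior.rt_sd
        rt = stats.truncnorm.rvs(a, b, loc=mu, scale=behavior.rt_sd, random_state=rng)
        saccade_time[is_hit] = sched_target[is_hit] + rt
        endpoint[is_hit] = "target_loc"
        gen_outcome[is_hit] = "hit"
    if is_miss.any():
        split = np.cumsum(behavior.miss_split)
        sub = (rng.random(n)[:, None] >= split[None, :]).sum(axis=1)
        no_sac = is_miss & (sub == 0)
        opp = is_miss & (sub == 1)
        elsw = is_miss & (sub == 2)
        gen_outcome[no_sac] = "miss_no_saccade"
        for m, role, label in ((opp, "opposite_cue_loc", "miss_opposite"),
                               (elsw, "elsewhere", "miss_elsewhere")):
            if m.any():
                lat = rt_lo + rng.random(m.sum()) * (rt_hi - rt_lo)
                saccade_time[m] = sched_target[m] + lat
                endpoint[m] = role
                gen_outcome[m] = label

    target_onset = np.where(is_break, np.nan, sched_target)

    return pd.DataFrame(
        {
            "trial_type": tt,
            "cue_contra": cue_contra,
            "cue_ipsi": cue_ipsi,
            "cue_set": cue_set,
            "fixation_onset": fixation_onset,
            "cue_onset": cue_onset,
            "cue_offset": cue_offset,
            "target_onset": target_onset,
            "target_side": target_side,
            "saccade_time": saccade_time,
            "saccade_endpoint_role": endpoint,
            "gen_outcome": gen_outcome,
            "_sched_target": sched_target,
        }
    )


def generate_trial(
    timing: TaskTimingParams,
    behavior: BehaviorParams,
    trial_type: str,
    rng: np.random.Generator,
) -> Trial:
    """Draw a single trial (times relative to trial start)."""
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial_type {trial_type!r}")
    row = _draw_trial_batch(timing, behavior, np.array([trial_type], dtype=object), rng)
    r = row.iloc[0]

    def _none_if_nan(x):
        return None if pd.isna(x) else float(x)

    return Trial(
        trial_id=0,
        trial_type=r["trial_type"],
        cue_contra=r["cue_contra"],
        cue_ipsi=r["cue_ipsi"],
        cue_set=int(r["cue_set"]),
        fixation_onset=float(r["fixation_onset"]),
        cue_onset=float(r["cue_onset"]),
        cue_offset=float(r["cue_offset"]),
        target_onset=_none_if_nan(r["target_onset"]),
        target_side=r["target_side"],
        saccade_time=_none_if_nan(r["saccade_time"]),
        saccade_endpoint_role=r["saccade_endpoint_role"],
        gen_outcome=r["gen_outcome"],
    )


def epoch_gain_matrix(trials: pd.DataFrame, neuron: NeuronParams) -> np.ndarray:
    """Per-trial multiplicative rate gain exp(sum of active betas).

    Active betas: reward presence; reward-cue contralateral; punishment-cue
    contralateral when no reward cue is shown; +/- the secondary-punishment
    beta when a P cue appears contra/ipsi to a reward cue; the abort beta on
    abort trials.  Returns shape (n_trials,) — gains are epoch-constant.
    """
    r_present = (trials["cue_contra"] == "R") | (trials["cue_ipsi"] == "R")
    lin = np.where(r_present, neuron.beta_reward_present, 0.0)
    lin = lin + np.where(trials["cue_contra"] == "R", neuron.beta_reward_contra, 0.0)
    lin = lin + np.where(
        (trials["cue_contra"] == "P") & ~r_present, neuron.beta_punish_contra, 0.0
    )
    lin = lin + np.where(
        (trials["cue_contra"] == "P") & r_present,
        neuron.beta_punish_secondary_contra,
        0.0,
    )
    lin = lin + np.where(
        (trials["cue_ipsi"] == "P") & r_present,
        -neuron.beta_punish_secondary_contra,
        0.0,
    )
    outcome = trials["outcome_label"] if "outcome_label" in trials else trials["gen_outcome"]
    lin = lin + np.where(outcome == "abort", neuron.beta_abort, 0.0)
    return np.exp(lin)


def _spikes_for_trials(
    trials: pd.DataFrame, neuron: NeuronParams, rng: np.random.Generator
) -> np.ndarray:
    """Piecewise-constant Poisson spikes within the analysis span of each
    trial (session clock).  Spikes after an abort's saccade are suppressed."""
    gain = epoch_gain_matrix(trials, neuron)
    cue_onset = trials["cue_onset"].to_numpy(float)
    is_abort = (trials["gen_outcome"] == "abort").to_numpy()
    sacc = trials["saccade_time"].to_numpy(float)

    chunks = []
    for e, (start, end) in enumerate(EPOCH_WINDOWS_S):
        lam = np.maximum(neuron.baseline_rate[e] * gain, 0.0) * (end - start)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        trial_idx = np.repeat(np.arange(len(trials)), counts)
        t = cue_onset[trial_idx] + start + rng.random(total) * (end - start)
        # truncate abort trials at the fixation break
        keep = ~(is_abort[trial_idx] & (t >= sacc[trial_idx]))
        chunks.append(t[keep])
    if not chunks:
        return np.empty(0)
    return np.sort(np.concatenate(chunks))


def generate_spikes(
    trial: Trial | pd.Series, neuron: NeuronParams, rng: np.random.Generator
) -> np.ndarray:
    """Spike timestamps for one unit on one trial (same clock as the trial)."""
    if isinstance(trial, Trial):
        row = pd.DataFrame([vars(trial)])
    else:
        row = pd.DataFrame([trial])
    return _spikes_for_trials(row, neuron, rng)


def sample_population(
    n_units: int,
    seed_or_rng: int | np.random.Generator,
    *,
    mua_fraction: float = 0.46,
    baseline_mean: float = 8.0,
    baseline_sigma: float = 0.5,
    sd_reward_present: float = 0.35,
    sd_reward_contra: float = 0.35,
    punish_coupling: float = 0.5,
    sd_punish_noise: float = 0.12,
    sd_punish_secondary: float = 0.08,
    abort_coupling: float = -0.5,
    sd_abort_noise: float = 0.15,
) -> list[NeuronParams]:
    """Draw a heterogeneous unit population with coupled selectivity betas.

    beta_punish_contra is correlated with beta_reward_contra (coefficient
    ``punish_coupling``) and beta_abort with beta_reward_present (coefficient
    ``abort_coupling``, negative by default), emulating the population-level
    coupling between spatial-reward/spatial-punishment selectivity and the
    reward/abort selectivity relationship.  Set couplings to 0 and the sds as
    needed for null populations.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    units = []
    for i in range(n_units):
        kind = "MUA" if rng.random() < mua_fraction else "SUA"
        base = float(baseline_mean * np.exp(rng.normal(0, baseline_sigma)))
        if kind == "MUA":
            base *= 2.5  # multi-unit sites aggregate several neurons
        brp = rng.normal(0, sd_reward_present)
        brc = rng.normal(0, sd_reward_contra)
        bpc = punish_coupling * brc + rng.normal(0, sd_punish_noise)
        bab = abort_coupling * brp + rng.normal(0, sd_abort_noise)
        units.append(
            NeuronParams(
                unit_id=f"u{i:04d}",
                unit_kind=kind,
                baseline_rate=(base, base * 0.9, base * 0.85),
                beta_reward_present=float(brp),
                beta_reward_contra=float(brc),
                beta_punish_contra=float(bpc),
                beta_punish_secondary_contra=float(rng.normal(0, sd_punish_secondary)),
                beta_abort=float(bab),
            )
        )
    return units


def generate_session(
    n_trials: int,
    *,
    seed: int,
    timing: Optional[TaskTimingParams] = None,
    behavior: Optional[BehaviorParams] = None,
    neurons: Sequence[NeuronParams] = (),
    trial_types: Sequence[str] = TRIAL_TYPES,
    inter_trial_interval: float = 0.5,
    outcome_window: float = 1.1,
    max_repeat_rounds: int = 60,
) -> SessionData:
    """Generate a full session: ``n_trials`` scheduled trials plus a repeat
    of every false-alarm/abort trial (re-randomized configuration), laid out
    sequentially on a session clock, with spike trains for each unit.

    Deterministic given ``seed``: trial structure and each unit's spikes are
    drawn from independent child streams of the seed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    bad = [t for t in trial_types if t not in TRIAL_TYPES]
    if bad or not trial_types:
        raise ValueError(f"invalid trial_types {bad}")
    timing = timing or TaskTimingParams()
    behavior = behavior or BehaviorParams()

    ss = np.random.SeedSequence(seed)
    trial_ss, *unit_ss = ss.spawn(1 + len(neurons))
    rng = np.random.default_rng(trial_ss)

    types = np.asarray(trial_types, dtype=object)[
        rng.integers(0, len(trial_types), n_trials)
    ]
    rounds = []
    parents = None  # absolute ids of the trials each round repeats
    offset = 0
    tt = types
    for _ in range(max_repeat_rounds):
        df = _draw_trial_batch(timing, behavior, tt, rng)
        df.insert(0, "trial_id", np.arange(offset, offset + len(df)))
        df["repeated_from"] = parents if parents is not None else np.full(len(df), np.nan)
        broke = df["gen_outcome"].isin(["false_alarm", "abort"]).to_numpy()
        rounds.append(df)
        if not broke.any():
            break
        parents = df.loc[broke, "trial_id"].to_numpy(float)
        tt = df.loc[broke, "trial_type"].to_numpy()
        offset += len(df)
    else:  # pragma: no cover - would need a break probability near 1
        raise RuntimeError("repeat chain did not terminate")

    trials = pd.concat(rounds, ignore_index=True)

    # lay trials out on the session clock
    span = trials["_sched_target"].to_numpy() + outcome_window
    starts = np.concatenate([[0.0], np.cumsum(span + inter_trial_interval)[:-1]])
    for col in ("fixation_onset", "cue_onset", "cue_offset", "target_onset",
                "saccade_time", "_sched_target"):
        trials[col] = trials[col] + starts
    session_end = float(starts[-1] + span[-1])

    trials["repeated_from"] = trials["repeated_from"].astype("Int64")
    trials = trials.drop(columns="_sched_target")[TRIAL_COLUMNS]

    spikes: Dict[str, SpikeTrain] = {}
    for nrn, child in zip(neurons, unit_ss):
        unit_rng = np.random.default_rng(child)
        ts = _spikes_for_trials(trials, nrn, unit_rng)
        spikes[nrn.unit_id] = SpikeTrain(
            unit_id=nrn.unit_id,
            unit_kind=nrn.unit_kind,
            timestamps=ts,
            valid_interval=(0.0, session_end),
        )

    meta = {
        "seed": int(seed),
        "n_trials": int(n_trials),
        "n_total_trials": int(len(trials)),
        "n_neurons": len(neurons),
        "trial_types": list(trial_types),
        "contra_side": "right",  # left-hemisphere recording convention
        "session_end": session_end,
        "timing": vars(timing).copy(),
    }
    return SessionData(trials=trials, spikes=spikes, meta=meta)


def write_session(session: SessionData, out_dir: str | Path) -> None:
    """Write trials.csv, spikes.csv, session.json (times in seconds; empty
    string for absent values)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "trials.csv", index=False)
    rows = []
    for st in session.spikes.values():
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": st.unit_id,
                    "unit_kind": st.unit_kind,
                    "timestamp_s": st.timestamps,
                }
            )
        )
    spikes_df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["unit_id", "unit_kind", "timestamp_s"])
    )
    spikes_df.to_csv(out / "spikes.csv", index=False)
    with open(out / "session.json", "w") as fh:
        json.dump(session.meta, fh, indent=2, sort_keys=True)


def read_session(in_dir: str | Path) -> SessionData:
    """Read a session written by :func:`write_session`."""
    p = Path(in_dir)
    trials = pd.read_csv(p / "trials.csv")
    trials["repeated_from"] = trials["repeated_from"].astype("Int64")
    for col in ("saccade_endpoint_role", "gen_outcome", "outcome_label"):
        if col in trials:
            obj = trials[col].astype(object)
            trials[col] = obj.where(obj.notna(), None)
    with open(p / "session.json") as fh:
        meta = json.load(fh)
    spikes_df = pd.read_csv(p / "spikes.csv")
    spikes: Dict[str, SpikeTrain] = {}
    end = float(meta.get("session_end", np.inf))
    for (uid, kind), g in spikes_df.groupby(["unit_id", "unit_kind"], sort=True):
        spikes[str(uid)] = SpikeTrain(
            unit_id=str(uid),
            unit_kind=str(kind),
            timestamps=np.sort(g["timestamp_s"].to_numpy(float)),
            valid_interval=(0.0, end),
        )
    return SessionData(trials=trials, spikes=spikes, meta=meta)
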