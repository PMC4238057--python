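"""Pipeline orchestration: generate -> classify -> rate -> selectivity ->
population/behavior, with config, logging, and reproducible outputs.

Every stage consumes only tables produced by earlier stages, so a run can be
resumed from any written artifact; identical config + seed gives identical
CSV payloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import abort_contrasts, behavior_summary_table, rt_compare
from .epoch_rates import EPOCH_NAMES, rates_table
from .params import CUE_ROLES, TRIAL_TYPES, BehaviorParams, TaskTimingParams
from .population_stats import (
    cross_epoch_correlation,
    index_regression,
    multiple_index_regression,
    paired_indices,
    paired_magnitude_test,
    proportions_differ,
    sign_agreement,
    sign_agreement_score,
    slope_homogeneity,
)
from .selectivity import ALPHA, MIN_TRIALS, compute_selectivity, summarize_counts
from .synthetic_session import (
    SessionData,
    generate_session,
    read_session,
    sample_population,
    write_session,
)
from .trial_classification import classify_trials

__all__ = ["RunConfig", "run_pipeline", "population_summary", "analyze_session"]

logger = logging.getLogger(__name__)

#: index-pair relationships reported in the population summary, as
#: name -> (x comparison, y comparison)
INDEX_PAIRS = {
    "reward_vs_spatial_reward": ("reward", "spatial_reward"),
    "spatial_reward_vs_spatial_punishment": ("spatial_reward", "spatial_punishment"),
    "spatial_reward_vs_punishment_contra": ("spatial_reward", "punishment_contra"),
    "spatial_reward_vs_punishment_ipsi": ("spatial_reward", "punishment_ipsi"),
    "reward_vs_abort_Pcontra": ("reward", "abort_Pcontra"),
}


@dataclass
class RunConfig:
    seed: int = 0
    n_trials: int = 2000
    n_neurons: int = 50
    trial_types: Sequence[str] = TRIAL_TYPES
    alpha: float = ALPHA
    min_trials: int = MIN_TRIALS
    out_dir: str = "cueattn_run"
    timing: dict = field(default_factory=dict)      # TaskTimingParams overrides
    behavior: dict = field(default_factory=dict)    # BehaviorParams overrides
    population: dict = field(default_factory=dict)  # sample_population overrides

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def timing_params(self) -> TaskTimingParams:
        return TaskTimingParams(**self.timing)

    def behavior_params(self) -> BehaviorParams:
        kw = dict(self.behavior)
        for key in ("hit_rate", "rt_mean", "false_alarm_rate", "abort_rate"):
            if key in kw:  # YAML mappings arrive keyed "trial_type,cue"
                kw[key] = {tuple(str(k).split(",")): v for k, v in kw[key].items()}
        return BehaviorParams(**kw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def population_summary(results: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """All population statistics keyed by relationship / comparison / epoch.

    Entries that lack enough computed indices are recorded as null rather
    than raising, so sparse sessions still summarize.
    """
    out: dict = {"counts": {}, "regressions": {}, "cross_epoch": {}}
    counts = summarize_counts(results, alpha)
    for _, row in counts.iterrows():
        out["counts"].setdefault(row["comparison"], {})[row["epoch"]] = {
            "n": int(row["n"]),
            "n_positive_significant": int(row["n_positive_significant"]),
            "n_negative_significant": int(row["n_negative_significant"]),
            "p_binomial": row["p_binomial"],
        }

    def _sub(name):
        return results[results["comparison"] == name]

    for pair_name, (cx, cy) in INDEX_PAIRS.items():
        entry: dict = {"per_epoch": {}, "slope_homogeneity_p": None}
        groups = []
        for epoch in EPOCH_NAMES:
            m = paired_indices(
                _sub(cx)[_sub(cx)["epoch"] == epoch],
                _sub(cy)[_sub(cy)["epoch"] == epoch],
                on=("unit_id",),
            )
            if len(m) >= 3 and m["index_x"].nunique() > 1:
                reg = index_regression(m["index_x"], m["index_y"])
                entry["per_epoch"][epoch] = _jsonable(reg)
                groups.append((m["index_x"].to_numpy(), m["index_y"].to_numpy()))
            else:
                entry["per_epoch"][epoch] = None
        if len(groups) >= 2:
            try:
                entry["slope_homogeneity_p"] = slope_homogeneity(groups)
            except ValueError:
                pass
        out["regressions"][pair_name] = entry

    # does spatial-reward selectivity, more than reward selectivity, predict
    # spatial-punishment selectivity?
    multi = {}
    for epoch in EPOCH_NAMES:
        ep = results[results["epoch"] == epoch]
        m = paired_indices(
            ep[ep["comparison"] == "spatial_punishment"],
            ep[ep["comparison"] == "spatial_reward"],
            on=("unit_id",),
        ).merge(
            ep[ep["comparison"] == "reward"][["unit_id", "index"]].rename(
                columns={"index": "index_reward"}
            ),
            on="unit_id",
        )
        if len(m) >= 4:
            try:
                fit = multiple_index_regression(
                    m["index_x"], m["index_y"], m["index_reward"]
                )
                multi[epoch] = {
                    "beta_spatial_reward": fit.betas[0],
                    "beta_reward": fit.betas[1],
                    "p_betas": list(fit.p_betas),
                    "n": fit.n,
                }
            except ValueError:
                multi[epoch] = None
        else:
            multi[epoch] = None
    out["multiple_regression_spatial_punishment"] = multi

    sr, sp = _sub("spatial_reward"), _sub("spatial_punishment")
    out["sign_agreement_spatial"] = _jsonable(sign_agreement(sr, sp))
    m = paired_indices(sr, sp)
    out["paired_magnitude_p"] = (
        paired_magnitude_test(m["magnitude_x"], m["magnitude_y"]) if len(m) else None
    )
    # are spatial-punishment-selective sites rarer than spatial-reward ones?
    prop = {}
    for epoch in EPOCH_NAMES:
        a = sr[sr["epoch"] == epoch]
        b = sp[sp["epoch"] == epoch]
        if len(a) and len(b):
            try:
                prop[epoch] = proportions_differ(
                    int(a["significant"].sum()), len(a),
                    int(b["significant"].sum()), len(b),
                )
            except ValueError:
                prop[epoch] = None
        else:
            prop[epoch] = None
    out["selective_fraction_reward_vs_punishment_p"] = prop

    for name in ("reward", "spatial_reward", "spatial_punishment",
                 "punishment_contra", "punishment_ipsi"):
        try:
            out["cross_epoch"][name] = {
                k: _jsonable(v)
                for k, v in cross_epoch_correlation(results, name).items()
            }
        except ValueError:
            out["cross_epoch"][name] = None

    score = sign_agreement_score(sr, sp)
    out["sign_agreement_score_mean"] = float(score.mean()) if len(score) else None
    return _jsonable(out)


def _scatter_tables(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for pair_name, (cx, cy) in INDEX_PAIRS.items():
        m = paired_indices(
            results[results["comparison"] == cx],
            results[results["comparison"] == cy],
        )
        if m.empty:
            continue
        out[pair_name] = m[
            ["unit_id", "epoch", "index_x", "index_y", "significant_x", "significant_y"]
        ].rename(columns={"index_x": cx, "index_y": cy})
    return out


def analyze_session(
    session: SessionData,
    alpha: float = ALPHA,
    min_trials: int = MIN_TRIALS,
) -> dict:
    """Run classification, rates, selectivity, behavior and population stages
    on an in-memory session; returns a dict of tables/summaries."""
    trials = classify_trials(session.trials)
    out: dict = {"trials": trials}
    out["behavior_summary"] = behavior_summary_table(trials)
    tests = [abort_contrasts(trials, w) for w in (None, "cue", "delay")]
    rt_rows = []
    for tt in TRIAL_TYPES:
        if (trials["trial_type"] == tt).any():
            c1, c2 = CUE_ROLES[tt]
            try:
                p = rt_compare(trials, tt, c1, c2)
            except ValueError:
                p = np.nan
            rt_rows.append(
                {"contrast": f"RT {tt}: {c1} vs {c2}", "window": "", "p_raw": p,
                 "p_corrected": p}
            )
    out["behavior_tests"] = pd.concat(
        tests + [pd.DataFrame(rt_rows)], ignore_index=True
    )

    if session.spikes:
        rates = rates_table(trials, session.spikes)
        results = compute_selectivity(
            rates, trials, min_trials=min_trials, alpha=alpha
        )
        out["rates"] = rates
        out["selectivity"] = results
        out["selectivity_summary"] = summarize_counts(results, alpha)
        out["population_summary"] = population_summary(results, alpha)
        out["scatter"] = _scatter_tables(results)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline per config; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    neurons = sample_population(
        config.n_neurons,
        np.random.default_rng(np.random.SeedSequence([int(config.seed), 1])),
        **config.population,
    )
    session = generate_session(
        config.n_trials,
        seed=int(config.seed),
        timing=config.timing_params(),
        behavior=config.behavior_params(),
        neurons=neurons,
        trial_types=tuple(config.trial_types),
    )
    logger.info(
        "generated session: %d trials (%d scheduled), %d units",
        len(session.trials), config.n_trials, len(neurons),
    )

    res = analyze_session(session, alpha=config.alpha, min_trials=config.min_trials)
    session.trials = res["trials"]  # persist outcome_label/reinforcement
    write_session(session, out)

    res["behavior_summary"].to_csv(out / "behavior_summary.csv", index=False)
    res["behavior_tests"].to_csv(out / "behavior_tests.csv", index=False)
    if "rates" in res:
        res["rates"].to_csv(out / "rates.csv", index=False)
        res["selectivity"].to_csv(out / "selectivity.csv", index=False)
        res["selectivity_summary"].to_csv(out / "selectivity_summary.csv", index=False)
        with open(out / "population_summary.json", "w") as fh:
            json.dump(res["population_summary"], fh, indent=2, sort_keys=True)
        for name, df in res["scatter"].items():
            df.to_csv(out / f"scatter_{name}.csv", index=False)
        logger.info(
            "selectivity: %d rows across %d units",
            len(res["selectivity"]), res["selectivity"]["unit_id"].nunique(),
        )

    import scipy
    import statsmodels

    manifest = {
        "config": _jsonable(dataclasses.asdict(config)),
        "versions": {
            "cueattn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def stats_from_dir(in_dir: str | Path, out_dir: Optional[str | Path] = None) -> dict:
    """Re-run the analysis stages from a written session directory."""
    session = read_session(in_dir)
    res = analyze_session(session)
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        res["behavior_summary"].to_csv(outp / "behavior_summary.csv", index=False)
        res["behavior_tests"].to_csv(outp / "behavior_tests.csv", index=False)
        if "selectivity" in res:
            res["selectivity"].to_csv(outp / "selectivity.csv", index=False)
            res["selectivity_summary"].to_csv(
                outp / "selectivity_summary.csv", index=False
            )
            with open(outp / "population_summary.json", "w") as fh:
                json.dump(res["population_summary"], fh, indent=2, sort_keys=True)
    return res
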