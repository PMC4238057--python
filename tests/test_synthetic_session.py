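"""Generator behavior: delay distributions, outcome calibration, spike
statistics, session determinism and repeat bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import cueattn as ca
from cueattn.params import BehaviorParams, NeuronParams, TaskTimingParams
from cueattn.synthetic_session import (
    _draw_trial_batch,
    _spikes_for_trials,
    draw_delay,
    truncated_exponential_cdf,
)


class TestDrawDelay:
    def test_respects_bounds_with_mode_at_minimum(self, rng):
        d = draw_delay(500, 1500, 170, rng, size=100_000)
        assert d.min() >= 500 and d.max() <= 1500
        # exponential shape: the first 100 ms bin is the fullest
        hist, _ = np.histogram(d, bins=np.arange(500, 1501, 100))
        assert hist.argmax() == 0

    def test_mean_matches_quadrature_oracle(self, rng):
        lo, hi, scale = 400.0, 4000.0, 390.0
        pdf = lambda x: np.exp(-(x - lo) / scale)
        norm = integrate.quad(pdf, lo, hi)[0]
        expected_mean = integrate.quad(lambda x: x * pdf(x), lo, hi)[0] / norm
        d = draw_delay(lo, hi, scale, rng, size=1_000_000)
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - expected_mean) < 3 * se

    def test_cdf_matches_closed_form(self, rng):
        # P(draw <= 900) for the truncated shifted exponential on [400, 4000]
        lo, hi, scale = 400.0, 4000.0, 390.0
        expected = (1 - np.exp(-500 / scale)) / (1 - np.exp(-3600 / scale))
        d = draw_delay(lo, hi, scale, rng, size=1_000_000)
        p_hat = (d <= 900).mean()
        se = np.sqrt(expected * (1 - expected) / d.size)
        assert abs(p_hat - expected) < 3 * se
        assert truncated_exponential_cdf(900.0, lo, hi, scale) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [dict(scale_ms=0), dict(scale_ms=-5),
                                     dict(min_ms=900, max_ms=900)])
    def test_invalid_parameters_raise(self, rng, bad):
        kw = dict(min_ms=400, max_ms=4000, scale_ms=390)
        kw.update(bad)
        with pytest.raises(ValueError):
            draw_delay(kw["min_ms"], kw["max_ms"], kw["scale_ms"], rng)


class TestGenerateTrial:
    def test_degenerate_probabilities_force_hits(self, rng):
        behavior = BehaviorParams(
            hit_rate={k: 1.0 for k in BehaviorParams().hit_rate},
            false_alarm_rate={k: 0.0 for k in BehaviorParams().false_alarm_rate},
            abort_rate={k: 0.0 for k in BehaviorParams().abort_rate},
        )
        timing = TaskTimingParams()
        for _ in range(50):
            t = ca.generate_trial(timing, behavior, "R/N", rng)
            assert t.gen_outcome == "hit"
            assert t.saccade_endpoint_role == "target_loc"

    def test_trial_timing_invariants(self, rng):
        df = _draw_trial_batch(
            TaskTimingParams(), BehaviorParams(),
            np.full(5000, "R/P", dtype=object), rng,
        )
        assert np.allclose(df["cue_offset"] - df["cue_onset"], 0.3)
        delay = df["_sched_target"] - df["cue_offset"]
        assert (delay >= 0.4 - 1e-12).all() and (delay <= 4.0 + 1e-12).all()
        # the two cues on a trial are always distinct and match the type
        assert (df["cue_contra"] != df["cue_ipsi"]).all()
        assert set(map(tuple, df[["cue_contra", "cue_ipsi"]].to_numpy())) <= {
            ("R", "P"), ("P", "R")
        }

    def test_hit_rate_calibration_rp_trials(self, rng):
        df = _draw_trial_batch(
            TaskTimingParams(), BehaviorParams(),
            np.full(20_000, "R/P", dtype=object), rng,
        )
        cue_at = np.where(df["target_side"] == "contra", df["cue_contra"], df["cue_ipsi"])
        comp = df[df["gen_outcome"].isin(
            ["hit", "miss_no_saccade", "miss_opposite", "miss_elsewhere"]
        ) & (cue_at == "R")]
        p_hat = (comp["gen_outcome"] == "hit").mean()
        se = np.sqrt(0.879 * (1 - 0.879) / len(comp))
        assert abs(p_hat - 0.879) < 3 * se

    def test_miss_subtype_split(self, rng):
        behavior = BehaviorParams(
            hit_rate={k: 0.0 for k in BehaviorParams().hit_rate},
            false_alarm_rate={k: 0.0 for k in BehaviorParams().false_alarm_rate},
            abort_rate={k: 0.0 for k in BehaviorParams().abort_rate},
        )
        df = _draw_trial_batch(
            TaskTimingParams(), behavior, np.full(100_000, "P/N", dtype=object), rng
        )
        counts = df["gen_outcome"].value_counts(normalize=True)
        for label, p in [("miss_no_saccade", 0.61), ("miss_opposite", 0.28),
                         ("miss_elsewhere", 0.11)]:
            se = np.sqrt(p * (1 - p) / len(df))
            assert abs(counts[label] - p) < 4 * se

    def test_invalid_probability_rejected(self):
        hr = dict(BehaviorParams().hit_rate)
        hr[("R/P", "R")] = 1.2
        with pytest.raises(ValueError):
            BehaviorParams(hit_rate=hr)


def _spaced_trials(rng, trial_type, n, spacing=10.0):
    """Batch-drawn trials laid out on a session clock so spike windows from
    different trials cannot overlap."""
    df = _draw_trial_batch(
        TaskTimingParams(), BehaviorParams(), np.full(n, trial_type, dtype=object), rng
    )
    offs = np.arange(n) * spacing
    for col in ("fixation_onset", "cue_onset", "cue_offset", "target_onset",
                "saccade_time", "_sched_target"):
        df[col] = df[col] + offs
    return df.assign(trial_id=np.arange(n))


class TestGenerateSpikes:
    def test_poisson_mean_at_baseline(self, rng):
        trials = _spaced_trials(rng, "R/N", 20_000)
        nrn = NeuronParams("u0", baseline_rate=(10.0, 10.0, 10.0))
        ts = _spikes_for_trials(trials, nrn, rng)
        # completed trials carry 3 epochs x 10 sp/s x 0.3 s = 9 expected spikes
        comp = trials[~trials["gen_outcome"].isin(["false_alarm", "abort"])]
        counts = np.array([
            np.searchsorted(ts, c + 1.0) - np.searchsorted(ts, c + 0.1)
            for c in comp["cue_onset"].head(5000)
        ])
        assert counts.mean() == pytest.approx(9.0, abs=3 * counts.std() / np.sqrt(counts.size))
        # Fano factor of a Poisson count is 1
        assert 0.9 < counts.var() / counts.mean() < 1.1

    def test_reward_contra_gain_doubles_rate(self, rng):
        trials = _spaced_trials(rng, "R/N", 10_000)
        nrn = NeuronParams("u0", beta_reward_contra=np.log(2.0),
                           beta_reward_present=0.3)
        ts = _spikes_for_trials(trials, nrn, rng)
        comp = trials[~trials["gen_outcome"].isin(["false_alarm", "abort"])]
        counts = np.array([
            np.searchsorted(ts, c + 0.4) - np.searchsorted(ts, c + 0.1)
            for c in comp["cue_onset"]
        ])
        contra = comp["cue_contra"].to_numpy() == "R"
        ratio = counts[contra].mean() / counts[~contra].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_abort_spikes_suppressed_after_break(self, rng):
        trials = _spaced_trials(rng, "P/N", 4000)
        nrn = NeuronParams("u0", baseline_rate=(40.0, 40.0, 40.0))
        ts = _spikes_for_trials(trials, nrn, rng)
        ab = trials[trials["gen_outcome"] == "abort"]
        for _, row in ab.iterrows():
            n_after = np.searchsorted(ts, row["cue_onset"] + 1.0) - np.searchsorted(
                ts, row["saccade_time"]
            )
            assert n_after == 0


class TestGenerateSession:
    def test_deterministic_given_seed(self):
        neurons = ca.sample_population(3, 5)
        s1 = ca.generate_session(300, seed=17, neurons=neurons)
        s2 = ca.generate_session(300, seed=17, neurons=neurons)
        pd.testing.assert_frame_equal(s1.trials, s2.trials)
        for uid in s1.spikes:
            np.testing.assert_array_equal(
                s1.spikes[uid].timestamps, s2.spikes[uid].timestamps
            )
        s3 = ca.generate_session(300, seed=18, neurons=neurons)
        assert not s1.trials.equals(s3.trials)

    def test_trial_types_interleaved_uniformly(self):
        s = ca.generate_session(9000, seed=1)
        base = s.trials[s.trials["repeated_from"].isna()]
        freqs = base["trial_type"].value_counts(normalize=True)
        for tt in ca.TRIAL_TYPES:
            assert freqs[tt] == pytest.approx(1 / 3, abs=3 * np.sqrt((1 / 3) * (2 / 3) / len(base)))

    def test_every_break_has_a_repeat_successor(self):
        s = ca.generate_session(800, seed=2)
        t = s.trials
        broken = t.loc[t["gen_outcome"].isin(["false_alarm", "abort"]), "trial_id"]
        repeated_from = set(t["repeated_from"].dropna().astype(int))
        assert set(broken) == repeated_from
        # repeats come later in the session and re-randomize the delay
        rep = t[t["repeated_from"].notna()]
        parents = t.set_index("trial_id").loc[rep["repeated_from"].astype(int)]
        assert (rep["cue_onset"].to_numpy() > parents["cue_onset"].to_numpy()).all()

    def test_round_trip_through_csv(self, tmp_path, small_session):
        ca.write_session(small_session, tmp_path)
        back = ca.read_session(tmp_path)
        pd.testing.assert_frame_equal(
            back.trials, small_session.trials, check_dtype=False
        )
        assert set(back.spikes) == set(small_session.spikes)
        uid = next(iter(back.spikes))
        np.testing.assert_allclose(
            back.spikes[uid].timestamps, small_session.spikes[uid].timestamps
        )

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            ca.generate_session(0, seed=1)
        with pytest.raises(ValueError):
            ca.generate_session(10, seed=1, trial_types=("R/X",))
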