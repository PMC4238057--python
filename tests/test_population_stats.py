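"""Population statistics: regressions, ANCOVA, proportions, agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cueattn.population_stats import (
    AgreementResult,
    cross_epoch_correlation,
    index_regression,
    multiple_index_regression,
    paired_magnitude_test,
    proportion_vs_chance,
    proportions_differ,
    sign_agreement,
    sign_agreement_score,
    slope_homogeneity,
)


class TestIndexRegression:
    def test_identity_has_unit_slope(self, rng):
        x = rng.normal(0.5, 0.1, 50)
        fit = index_regression(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.p_slope < 1e-20

    def test_recovers_construction_slope(self, rng):
        x = rng.normal(0.5, 0.1, 300)
        y = 0.5 + 0.5 * (x - 0.5) + rng.normal(0, 0.05, 300)
        fit = index_regression(x, y)
        se = 0.05 / (0.1 * np.sqrt(300))  # slope SE for this construction
        assert abs(fit.slope - 0.5) < 2.5 * se

    def test_null_calibration(self, rng):
        hits = 0
        for _ in range(1000):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            hits += index_regression(x, y).p_slope < 0.05
        assert 0.03 < hits / 1000 < 0.07

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            index_regression([0.1, 0.2], [0.1, 0.2])


class TestMultipleRegression:
    def test_noise_covariate_gets_zero_beta(self, rng):
        x1 = rng.normal(size=400)
        x2 = rng.normal(size=400)
        fit = multiple_index_regression(x1, x1, x2)
        assert fit.betas[0] == pytest.approx(1.0, abs=0.01)
        assert abs(fit.betas[1]) < 0.01

    def test_recovers_constructed_betas(self, rng):
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 0.3 * x1 + 0.1 * x2 + rng.normal(0, 0.5, n)
        fit = multiple_index_regression(y, x1, x2)
        sd_y = np.sqrt(0.3**2 + 0.1**2 + 0.25)
        se = 0.5 / sd_y / np.sqrt(n)
        assert abs(fit.betas[0] - 0.3 / sd_y) < 3 * se
        assert abs(fit.betas[1] - 0.1 / sd_y) < 3 * se

    def test_betas_invariant_to_affine_rescaling(self, rng):
        y = rng.normal(size=100)
        x1 = rng.normal(size=100)
        x2 = rng.normal(size=100)
        f1 = multiple_index_regression(y, x1, x2)
        f2 = multiple_index_regression(3 * y - 1, 100 * x1 + 5, -0.01 * x2)
        assert f1.betas[0] == pytest.approx(f2.betas[0])
        assert f1.betas[1] == pytest.approx(-f2.betas[1])

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError):
            multiple_index_regression(rng.normal(size=50), x, 2 * x + 1)


class TestSlopeHomogeneity:
    def test_identical_groups_not_flagged(self, rng):
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(0, 0.3, 200)
        assert slope_homogeneity([(x, y), (x, y)]) > 0.9

    def test_detects_different_slopes(self, rng):
        flagged = 0
        for _ in range(20):
            x1 = rng.normal(size=200)
            x2 = rng.normal(size=200)
            g1 = (x1, 0.5 * x1 + rng.normal(0, 0.3, 200))
            g2 = (x2, 0.0 * x2 + rng.normal(0, 0.3, 200))
            flagged += slope_homogeneity([g1, g2]) < 0.05
        assert flagged >= 18

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(400):
            x1, x2 = rng.normal(size=60), rng.normal(size=60)
            g1 = (x1, 0.3 * x1 + rng.normal(0, 0.3, 60))
            g2 = (x2, 0.3 * x2 + rng.normal(0, 0.3, 60))
            ps.append(slope_homogeneity([g1, g2]))
        # Kolmogorov-Smirnov against Uniform(0, 1)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            slope_homogeneity([(np.ones(5), np.arange(5.0)),
                               (np.arange(5.0), np.arange(5.0))])


class TestProportionTests:
    def test_chance_count_is_central(self):
        assert proportion_vs_chance(5, 100, 0.05) == pytest.approx(1.0)

    def test_table1_style_excess_is_extreme(self):
        # 26 + 22 = 48 significant of 345 at alpha = 0.05
        assert proportion_vs_chance(48, 345, 0.05) < 1e-4

    def test_matches_bruteforce_binomial_sum(self):
        for k, n, p0 in [(0, 20, 0.05), (3, 17, 0.2), (48, 345, 0.05)]:
            pk = stats.binom.pmf(np.arange(n + 1), n, p0)
            brute = pk[pk <= pk[k] * (1 + 1e-7)].sum()
            assert proportion_vs_chance(k, n, p0) == pytest.approx(min(brute, 1.0))

    def test_equal_proportions_not_flagged(self):
        assert proportions_differ(50, 1000, 50, 1000) == pytest.approx(1.0)

    def test_selective_population_sizes_differ(self):
        # spatial-reward 152/345 vs spatial-punishment 48/345 selective sites
        assert proportions_differ(152, 345, 48, 345) < 1e-4

    def test_chisq_agrees_with_fisher_on_small_tables(self):
        # expected success count (20 * 4 / 40 = 2) < 5 -> Fisher fallback
        p_auto = proportions_differ(3, 20, 1, 20, method="auto")
        p_fisher = stats.fisher_exact([[3, 17], [1, 19]])[1]
        assert p_auto == pytest.approx(p_fisher)
        # large-expected-count tables agree with Fisher in order of magnitude
        p_chi = proportions_differ(30, 100, 10, 100)
        p_f2 = stats.fisher_exact([[30, 70], [10, 90]])[1]
        assert abs(np.log10(p_chi) - np.log10(p_f2)) < 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            proportions_differ(0, 10, 0, 10)


class TestPairedMagnitude:
    def test_identical_vectors_give_one(self):
        x = np.linspace(0, 0.4, 30)
        assert paired_magnitude_test(x, x) == 1.0

    def test_uniform_shift_is_extreme(self, rng):
        x = rng.uniform(0, 0.4, 100)
        assert paired_magnitude_test(x + 0.05, x) < 1e-5

    def test_antisymmetric_perturbation_is_null(self, rng):
        x = rng.uniform(0.1, 0.4, 100)
        delta = np.resize([0.02, -0.02], 100)
        assert paired_magnitude_test(x + delta, x) > 0.5


def _results_frame(unit_ids, epochs, indices, sig, comparison="c"):
    return pd.DataFrame(
        {
            "unit_id": unit_ids,
            "comparison": comparison,
            "epoch": epochs,
            "index": indices,
            "p_value": 0.01,
            "n_A": 20,
            "n_B": 20,
            "significant": sig,
            "magnitude": np.abs(np.asarray(indices) - 0.5),
        }
    )


class TestSignAgreement:
    def test_perfect_agreement(self):
        x = _results_frame(["a", "b"], ["E1", "E1"], [0.7, 0.3], [True, True])
        y = _results_frame(["a", "b"], ["E1", "E1"], [0.6, 0.4], [True, True])
        res = sign_agreement(x, y)
        assert res.proportion == 1.0 and res.n_both_significant == 2

    def test_published_scale_example(self):
        # 54 matched of 64 doubly significant responses
        n, k = 64, 54
        units = [f"u{i}" for i in range(n)]
        xi = [0.7] * n
        yi = [0.7] * k + [0.3] * (n - k)
        x = _results_frame(units, ["E1"] * n, xi, [True] * n)
        y = _results_frame(units, ["E1"] * n, yi, [True] * n)
        res = sign_agreement(x, y)
        assert res.n_matched == 54
        assert res.p_binomial < 1e-7
        assert res.p_binomial == pytest.approx(stats.binomtest(54, 64, 0.5).pvalue)

    def test_null_populations_agree_at_half(self, rng):
        props = []
        for _ in range(300):
            n = 40
            units = [f"u{i}" for i in range(n)]
            x = _results_frame(units, ["E1"] * n, rng.uniform(0.2, 0.8, n), [True] * n)
            y = _results_frame(units, ["E1"] * n, rng.uniform(0.2, 0.8, n), [True] * n)
            props.append(sign_agreement(x, y).proportion)
        assert np.mean(props) == pytest.approx(0.5, abs=0.02)

    def test_symmetric_in_arguments(self, rng):
        n = 30
        units = [f"u{i}" for i in range(n)]
        x = _results_frame(units, ["E1"] * n, rng.uniform(0.2, 0.8, n),
                           rng.random(n) < 0.7)
        y = _results_frame(units, ["E1"] * n, rng.uniform(0.2, 0.8, n),
                           rng.random(n) < 0.7)
        assert sign_agreement(x, y).proportion == sign_agreement(y, x).proportion

    def test_empty_result_marker(self):
        x = _results_frame(["a"], ["E1"], [0.7], [False])
        res = sign_agreement(x, x)
        assert res == AgreementResult(0, 0, np.nan, np.nan) or res.n_both_significant == 0


class TestSignAgreementScore:
    @pytest.mark.parametrize(
        "ix, iy, expected",
        [(0.7, 0.7, 0.04), (0.7, 0.3, -0.04), (0.5, 0.9, 0.0), (0.3, 0.3, 0.04)],
    )
    def test_single_epoch_arithmetic(self, ix, iy, expected):
        x = _results_frame(["a"], ["E1"], [ix], [True])
        y = _results_frame(["a"], ["E1"], [iy], [True])
        score = sign_agreement_score(x, y)
        assert score["a"] == pytest.approx(expected)

    def test_averages_over_epochs(self):
        x = _results_frame(["a", "a"], ["E1", "E2"], [0.7, 0.7], [True, True])
        y = _results_frame(["a", "a"], ["E1", "E2"], [0.7, 0.3], [True, True])
        assert sign_agreement_score(x, y)["a"] == pytest.approx(0.0)


class TestCrossEpoch:
    def test_perfect_persistence_gives_unit_slope(self, rng):
        n = 60
        idx = rng.uniform(0.2, 0.8, n)
        frames = [
            _results_frame([f"u{i}" for i in range(n)], [e] * n, idx, [True] * n)
            for e in ("E1", "E2", "E3")
        ]
        res = cross_epoch_correlation(pd.concat(frames, ignore_index=True), "c")
        assert res["E1->E2"].slope == pytest.approx(1.0, abs=1e-10)
        assert res["E2->E3"].slope == pytest.approx(1.0, abs=1e-10)

    def test_independent_epochs_give_flat_slope(self, rng):
        n = 400
        frames = [
            _results_frame(
                [f"u{i}" for i in range(n)], [e] * n,
                rng.uniform(0.2, 0.8, n), [True] * n,
            )
            for e in ("E1", "E2", "E3")
        ]
        res = cross_epoch_correlation(pd.concat(frames, ignore_index=True), "c")
        assert abs(res["E1->E2"].slope) < 0.15
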