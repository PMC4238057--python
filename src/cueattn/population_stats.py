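"""Population-level statistics relating selectivity indices.

Covers the cross-index relationships the analysis reports: ordinary linear
regression between paired selectivity indices, multiple regression with
standardized coefficients, slope-homogeneity (ANCOVA interaction F) tests
across epochs/subjects/unit kinds, exact binomial tests of significant-site
counts against the chance rate, chi-square comparisons of selective-site
proportions, paired signed-rank comparisons of selectivity magnitudes, and
sign-agreement measures between two index families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "RegressionResult",
    "AgreementResult",
    "index_regression",
    "multiple_index_regression",
    "slope_homogeneity",
    "proportion_vs_chance",
    "proportions_differ",
    "paired_magnitude_test",
    "sign_agreement",
    "sign_agreement_score",
    "cross_epoch_correlation",
    "paired_indices",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_slope: float
    r: float
    n: int
    betas: tuple = field(default=())  # standardized, multiple regression only
    p_betas: tuple = field(default=())


@dataclass(frozen=True)
class AgreementResult:
    n_both_significant: int
    n_matched: int
    proportion: float
    p_binomial: float


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def index_regression(x_indices, y_indices) -> RegressionResult:
    """OLS fit of y on x with a two-sided t-test on the slope.

    Pairs with either value missing are dropped; requires n >= 3.
    """
    x, y = _clean_pairs(x_indices, y_indices)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = stats.linregress(x, y)
    p = fit.pvalue if not np.isnan(fit.pvalue) else 1.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_slope=float(min(max(p, np.finfo(float).tiny), 1.0)),
        r=float(fit.rvalue),
        n=int(x.size),
    )


def multiple_index_regression(y, x1, x2) -> RegressionResult:
    """Fit y ~ x1 + x2 on z-scored variables; report standardized betas.

    Standardization puts both coefficients on the same scale so their
    magnitudes are directly comparable.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x1) | np.isnan(x2))
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    if y.size < 4:
        raise ValueError("need at least 4 complete triples")
    for v, name in ((x1, "x1"), (x2, "x2"), (y, "y")):
        if np.std(v) == 0:
            raise ValueError(f"{name} is constant")
    if abs(np.corrcoef(x1, x2)[0, 1]) > 1 - 1e-12:
        raise ValueError("x1 and x2 are perfectly collinear")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    X = sm.add_constant(np.column_stack([z(x1), z(x2)]))
    fit = sm.OLS(z(y), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_slope=float(fit.pvalues[1]),
        r=float(np.sqrt(max(fit.rsquared, 0.0))),
        n=int(y.size),
        betas=tuple(float(b) for b in fit.params[1:]),
        p_betas=tuple(float(p) for p in fit.pvalues[1:]),
    )


def slope_homogeneity(groups: Sequence[tuple]) -> float:
    """ANCOVA test of equal slopes across groups.

    Fits the pooled model y ~ group + x + group:x and returns the F-test
    p-value of the group-by-x interaction; a small p means the regression
    slope differs between groups (epochs, subjects, unit kinds, ...).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    for gi, (x, y) in enumerate(groups):
        x, y = _clean_pairs(x, y)
        if x.size < 3 or np.ptp(x) == 0:
            raise ValueError(f"group {gi} is degenerate")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": str(gi)}))
    df = pd.concat(frames, ignore_index=True)
    fit = smf.ols("y ~ C(g) * x", data=df).fit()
    tbl = anova_lm(fit, typ=2)
    p = float(tbl.loc["C(g):x", "PR(>F)"])
    return min(max(p, np.finfo(float).tiny), 1.0) if np.isfinite(p) else 1.0


def proportion_vs_chance(k_significant: int, n: int, p0: float = 0.05) -> float:
    """Two-sided exact binomial test of k successes in n against rate p0."""
    if not 0 <= k_significant <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return 1.0
    return float(stats.binomtest(k_significant, n, p0).pvalue)


def proportions_differ(
    k1: int, n1: int, k2: int, n2: int, method: str = "auto"
) -> float:
    """Compare two proportions via a 2x2 chi-square test (no continuity
    correction); with ``method='auto'`` falls back to Fisher's exact test
    when any expected cell count is below 5."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.min() < 0:
        raise ValueError("counts must satisfy 0 <= k <= n")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero margin)")
    expected = stats.contingency.expected_freq(table)
    if method == "fisher" or (method == "auto" and expected.min() < 5):
        return float(stats.fisher_exact(table.astype(int))[1])
    chi2 = stats.chi2_contingency(table, correction=False)
    return float(chi2.pvalue)


def paired_magnitude_test(mag_x, mag_y) -> float:
    """Two-sided Wilcoxon signed-rank p on paired magnitudes; p = 1 when all
    differences vanish."""
    x, y = _clean_pairs(mag_x, mag_y)
    if x.size == 0:
        raise ValueError("no complete pairs")
    d = x - y
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)


def paired_indices(
    results_x: pd.DataFrame,
    results_y: pd.DataFrame,
    on: Sequence[str] = ("unit_id", "epoch"),
) -> pd.DataFrame:
    """Inner-join two selectivity tables on (unit, epoch), suffixing columns
    _x and _y; the raw material for regressions and agreement measures."""
    return results_x.merge(results_y, on=list(on), suffixes=("_x", "_y"))


def sign_agreement(
    results_x: pd.DataFrame,
    results_y: pd.DataFrame,
    require_significance: bool = True,
) -> AgreementResult:
    """Fraction of paired responses whose indices fall on the same side of
    0.5, among pairs where both are significant (if required), with an exact
    binomial test against 0.5.  An index exactly at 0.5 counts as unmatched.
    """
    m = paired_indices(results_x, results_y)
    if require_significance:
        m = m[m["significant_x"] & m["significant_y"]]
    n = len(m)
    if n == 0:
        return AgreementResult(0, 0, np.nan, np.nan)
    same = ((m["index_x"] > 0.5) & (m["index_y"] > 0.5)) | (
        (m["index_x"] < 0.5) & (m["index_y"] < 0.5)
    )
    k = int(same.sum())
    return AgreementResult(n, k, k / n, float(stats.binomtest(k, n, 0.5).pvalue))


def sign_agreement_score(
    spatial_reward_results: pd.DataFrame,
    spatial_punishment_results: pd.DataFrame,
) -> pd.Series:
    """Per-unit sign-agreement score: the product of the two selectivity
    magnitudes |index - 0.5|, signed + when the indices agree in sign and -
    when they disagree, averaged over the epochs where both exist.  Zero when
    either index sits exactly at 0.5."""
    m = paired_indices(spatial_reward_results, spatial_punishment_results)
    if m.empty:
        return pd.Series(dtype=float, name="sign_agreement_score")
    dx = m["index_x"] - 0.5
    dy = m["index_y"] - 0.5
    score = np.sign(dx) * np.sign(dy) * dx.abs() * dy.abs()
    out = score.groupby(m["unit_id"].to_numpy()).mean()
    out.name = "sign_agreement_score"
    out.index.name = "unit_id"
    return out


def cross_epoch_correlation(
    results: pd.DataFrame,
    comparison: str,
    epoch_pairs: Sequence[tuple[str, str]] = (("E1", "E2"), ("E2", "E3")),
) -> dict[str, RegressionResult]:
    """Regression of a comparison's indices between adjacent epochs,
    pairing by unit."""
    sub = results[results["comparison"] == comparison]
    out = {}
    for e1, e2 in epoch_pairs:
        a = sub[sub["epoch"] == e1][["unit_id", "index"]]
        b = sub[sub["epoch"] == e2][["unit_id", "index"]]
        m = a.merge(b, on="unit_id", suffixes=("_1", "_2"))
        out[f"{e1}->{e2}"] = index_regression(m["index_1"], m["index_2"])
    return out
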