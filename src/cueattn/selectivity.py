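"""ROC selectivity indices and rank-test significance per condition split.

The selectivity index for a unit, comparison, and epoch is the area under
the ROC curve obtained by sweeping a firing-rate criterion over the two
trial-condition rate distributions — equivalently the Mann-Whitney AUC

    index = [#(a > b) + 0.5 #(a = b)] / (n_A n_B)

over all cross-pairs, with 0.5 meaning no discrimination and values above
0.5 meaning the first-named condition carries higher rates.  Significance is
assessed with a two-sided rank-sum test at alpha = 0.05, and an index is
computed only when at least 15 trials contribute to each distribution.

Condition splits:

* ``reward``            — reward cue shown (R/P or R/N) vs absent (P/N)
* ``spatial_reward``    — reward cue contralateral vs ipsilateral (R-present)
* ``spatial_punishment``— punishment cue contra vs ipsi, P/N trials only
* ``punishment_contra`` — R/P vs R/N with the reward cue ipsilateral
  (does a contralateral P cue, vs N cue, modulate rates?)
* ``punishment_ipsi``   — R/P vs R/N with the reward cue contralateral
* ``abort_*``           — abort vs completed trials within each of
  R-contra, R-ipsi (R-present trials) and P-contra, P-ipsi (P/N trials)

Abort-trial rates enter the abort comparisons with their truncated
durations; completed-trial rates obey the target-intrusion rule upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .epoch_rates import EPOCH_NAMES, STATUS_INCLUDED

__all__ = [
    "COMPARISONS",
    "SelectivityResult",
    "roc_index",
    "rank_test_p",
    "trial_conditions",
    "compute_selectivity",
    "summarize_counts",
    "MIN_TRIALS",
    "ALPHA",
]

logger = logging.getLogger(__name__)

MIN_TRIALS = 15
ALPHA = 0.05

#: combined sample size at or below which the rank-sum p is computed exactly
#: (when the pooled rates are tie-free)
EXACT_N = 20


@dataclass(frozen=True)
class SelectivityResult:
    unit_id: str
    comparison: str
    epoch: str
    index: float
    p_value: float
    n_A: int
    n_B: int
    significant: bool
    magnitude: float


def roc_index(rates_A: np.ndarray, rates_B: np.ndarray) -> float:
    """Mann-Whitney AUC of A over B (ties count half).

    Computed from tie-aware midranks: with R_A the rank sum of group A in
    the pooled sample, U_A = R_A - n_A(n_A+1)/2 and index = U_A/(n_A n_B).
    """
    a = np.asarray(rates_A, dtype=float)
    b = np.asarray(rates_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u_a / (a.size * b.size))


def rank_test_p(rates_A: np.ndarray, rates_B: np.ndarray) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value with tie correction.

    Exact enumeration for combined n <= 20 without ties; tie-corrected
    normal approximation otherwise.  Returns a value in (0, 1].
    """
    a = np.asarray(rates_A, dtype=float)
    b = np.asarray(rates_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_N and not has_ties) else "asymptotic"
    p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def trial_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-level condition flags used by the comparison splits.

    Requires a classified trial table (``outcome_label``).  Indexed by
    trial_id.
    """
    t = trials
    cc = t["cue_contra"].astype(object)
    ci = t["cue_ipsi"].astype(object)
    label = t["outcome_label"]
    out = pd.DataFrame(
        {
            "trial_type": t["trial_type"].to_numpy(),
            "completed": label.isin(
                ["hit", "miss_no_saccade", "miss_opposite", "miss_elsewhere"]
            ).to_numpy(),
            "abort": (label == "abort").to_numpy(),
            "r_present": ((cc == "R") | (ci == "R")).to_numpy(),
            "r_contra": (cc == "R").to_numpy(),
            "r_ipsi": (ci == "R").to_numpy(),
            "p_contra": (cc == "P").to_numpy(),
            "p_ipsi": (ci == "P").to_numpy(),
        },
        index=pd.Index(t["trial_id"].to_numpy(), name="trial_id"),
    )
    return out


def _analysable(c: pd.DataFrame) -> pd.Series:
    return c["completed"]


# name -> (group_A predicate, group_B predicate); index > 0.5 means
# group A (first-named condition) fires more
COMPARISONS: Mapping[str, tuple[Callable, Callable]] = {
    "reward": (
        lambda c: c["completed"] & c["r_present"],
        lambda c: c["completed"] & ~c["r_present"],
    ),
    "spatial_reward": (
        lambda c: c["completed"] & c["r_contra"],
        lambda c: c["completed"] & c["r_ipsi"],
    ),
    "spatial_punishment": (
        lambda c: c["completed"] & (c["trial_type"] == "P/N") & c["p_contra"],
        lambda c: c["completed"] & (c["trial_type"] == "P/N") & c["p_ipsi"],
    ),
    "punishment_contra": (
        lambda c: c["completed"] & (c["trial_type"] == "R/P") & c["r_ipsi"],
        lambda c: c["completed"] & (c["trial_type"] == "R/N") & c["r_ipsi"],
    ),
    "punishment_ipsi": (
        lambda c: c["completed"] & (c["trial_type"] == "R/P") & c["r_contra"],
        lambda c: c["completed"] & (c["trial_type"] == "R/N") & c["r_contra"],
    ),
    "abort_Rcontra": (
        lambda c: c["abort"] & c["r_contra"],
        lambda c: c["completed"] & c["r_contra"],
    ),
    "abort_Ripsi": (
        lambda c: c["abort"] & c["r_ipsi"],
        lambda c: c["completed"] & c["r_ipsi"],
    ),
    "abort_Pcontra": (
        lambda c: c["abort"] & (c["trial_type"] == "P/N") & c["p_contra"],
        lambda c: c["completed"] & (c["trial_type"] == "P/N") & c["p_contra"],
    ),
    "abort_Pipsi": (
        lambda c: c["abort"] & (c["trial_type"] == "P/N") & c["p_ipsi"],
        lambda c: c["completed"] & (c["trial_type"] == "P/N") & c["p_ipsi"],
    ),
}


def compute_selectivity(
    rates: pd.DataFrame,
    trials: pd.DataFrame,
    comparisons: Optional[Sequence[str]] = None,
    epochs: Sequence[str] = EPOCH_NAMES,
    min_trials: int = MIN_TRIALS,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One SelectivityResult row per (unit, comparison, epoch) with at least
    ``min_trials`` included rates in each group; under-filled cells are
    omitted (reason logged at DEBUG, tallied at INFO)."""
    names = list(comparisons) if comparisons is not None else list(COMPARISONS)
    for nm in names:
        if nm not in COMPARISONS:
            raise ValueError(f"unknown comparison {nm!r}")

    cond = trial_conditions(trials)
    # per-comparison trial codes: 1 = group A, 2 = group B, 0 = unused
    code_cols = []
    for nm in names:
        pred_a, pred_b = COMPARISONS[nm]
        mask_a, mask_b = pred_a(cond).to_numpy(), pred_b(cond).to_numpy()
        if (mask_a & mask_b).any():
            raise AssertionError(f"comparison {nm} groups overlap")
        code_cols.append(mask_a.astype(np.int8) + 2 * mask_b.astype(np.int8))
    code_matrix = np.column_stack(code_cols)

    inc = rates[rates["status"] == STATUS_INCLUDED]
    rows = []
    n_omitted = 0
    for (unit, epoch), g in inc.groupby(["unit_id", "epoch"], sort=True):
        if epoch not in epochs:
            continue
        tid = g["trial_id"].to_numpy()
        rate = g["rate"].to_numpy(float)
        pos = cond.index.get_indexer(tid)
        known = pos >= 0
        for j, nm in enumerate(names):
            codes = np.zeros(len(tid), dtype=np.int8)
            codes[known] = code_matrix[pos[known], j]
            a = rate[codes == 1]
            b = rate[codes == 2]
            if a.size < min_trials or b.size < min_trials:
                n_omitted += 1
                logger.debug(
                    "omitting %s/%s/%s: n_A=%d n_B=%d < %d",
                    unit, nm, epoch, a.size, b.size, min_trials,
                )
                continue
            idx = roc_index(a, b)
            p = rank_test_p(a, b)
            rows.append(
                {
                    "unit_id": unit,
                    "comparison": nm,
                    "epoch": epoch,
                    "index": idx,
                    "p_value": p,
                    "n_A": a.size,
                    "n_B": b.size,
                    "significant": p < alpha,
                    "magnitude": abs(idx - 0.5),
                }
            )
    if n_omitted:
        logger.info("omitted %d under-filled selectivity cells", n_omitted)
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "comparison", "epoch", "index", "p_value",
            "n_A", "n_B", "significant", "magnitude",
        ],
    )


def summarize_counts(results: pd.DataFrame, p0: float = ALPHA) -> pd.DataFrame:
    """Counts of significantly positive/negative sites per comparison and
    epoch, with an exact binomial test of the total significant fraction
    against the chance rate p0."""
    from .population_stats import proportion_vs_chance

    rows = []
    for (nm, epoch), g in results.groupby(["comparison", "epoch"], sort=True):
        n = len(g)
        pos = int((g["significant"] & (g["index"] > 0.5)).sum())
        neg = int((g["significant"] & (g["index"] < 0.5)).sum())
        rows.append(
            {
                "comparison": nm,
                "epoch": epoch,
                "n": n,
                "n_positive_significant": pos,
                "n_negative_significant": neg,
                "p_binomial": proportion_vs_chance(pos + neg, n, p0) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
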