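# Methods

## Scope and data model

The pipeline operates on two plain-text tables per session: a trial event
table (one row per presented trial: trial type, cue-by-hemifield
configuration, cue set, event times in seconds on a session clock, scheduled
target side, saccade time and discrete endpoint role) and a spike table (unit
id, SUA/MUA flag, timestamp). Laterality is reduced to labels: recordings are
assumed to come from one hemisphere (left, by convention), so "contra" is a
fixed hemifield per session and no angular geometry survives past event
extraction. Saccade endpoints likewise arrive as discrete roles
(`target_loc`, `opposite_cue_loc`, `elsewhere`); the 3° acceptance windows of
the task are the responsibility of whatever produced the events — here, the
generator.

## Task timing model

Fixation (500–1500 ms) and target delay (400–4000 ms, measured from cue
offset) are modeled as shifted exponentials truncated by rejection
resampling: min + Exp(scale), redrawn while above max, with scales 170 ms
and 390 ms. "Scale" is read as the mean of the unshifted exponential part; an
exponential "λ" over a bounded range is otherwise ambiguous, and the task's
derived timing folklore (46% of targets in the third epoch, ~23% blind-chance
performance) is not jointly reconcilable with any single reading, so those
derived numbers are deliberately not treated as calibration constraints.
`chance_performance` documents its own convention: the best fixed-time blind
saccade hits with probability 0.5·(F(t−0.1) − F(t−0.6)) under the delay CDF
F, maximized numerically over t.

## Behavioral outcome model

Per presented trial, mutually exclusive pre-target break events are drawn
first: a false alarm toward either cue (per-trial probabilities per trial
type and cue role) or an abort in the cue window (0–300 ms, uniform) or the
delay window (300 ms to the scheduled target onset, uniform). Surviving
trials complete: hit with the calibrated probability for the cue at the
target location, otherwise a miss subtyped 61/28/11 (no saccade / opposite
cue location / elsewhere), applied globally since the split is only reported
pooled. Hit reaction times are normal, truncated to the 100–600 ms response
window, sd 50 ms; the normal's location is solved (Brent) so the *truncated*
mean equals the calibrated mean — naive truncation would bias the recovered
mean RT by ~4 ms at the fastest condition. Broken trials are re-queued with
fully re-randomized configuration until a completed presentation results, so
per-presentation break frequencies equal their parameters while no scheduled
trial can be avoided.

Default calibration is the published session-pooled behavior of this task
(hit rates 0.879/0.362, 0.896/0.288, 0.744/0.597; RT means 0.189/0.266,
0.187/0.277, 0.222/0.247 s; false-alarm rates 0.333/0.034, 0.353/0.023,
0.147/0.097; abort totals per trial type from the subject with the larger
rates: 0.082/0.069/0.127, with the other subject's 0.012/0.009/0.028
available as a preset). Only per-type abort *totals* are published; the
split between the cue and delay windows is a package convention
(cue-window fraction 0.25 for the default subject, whose value-dependent
abort pattern was expressed during the delay; 0.75 for the other).
The Fig-6-style "delay" measurement window is 300–1000 ms, while generated
delay aborts extend to the scheduled target onset; the pooled abort
frequency (`window=None`) therefore counts any pre-target abort and is the
quantity that matches the per-type totals.

## Spike model

Spike trains are piecewise-constant inhomogeneous Poisson processes within
the three analysis epochs after cue onset. Epoch rate = baseline(epoch) ×
exp(Σ active betas), with betas activated by reward presence, reward-cue
laterality, punishment-cue laterality (primary, i.e. no reward cue present;
and secondary, ± for a P cue contra/ipsi to a reward cue), and abort
propensity; spikes after an abort's fixation break are suppressed. No onset
latency transient is modeled beyond the 100 ms epoch offset, and no spikes
are generated outside the 100–1000 ms analysis span — every downstream
statistic operates on epoch means, so finer temporal structure would be
untestable decoration. `sample_population` draws heterogeneous populations
with lognormal baselines (MUA sites 2.5× hotter), independent normal reward
betas, and two couplings that create the population structure of interest:
spatial-punishment betas correlated with spatial-reward betas (default
coefficient 0.5) and abort betas anti-correlated with reward betas (default
−0.5). Setting the couplings to zero yields null-structured populations.

What the generator does *not* emulate: continuous eye traces, slow drifts in
excitability or attention, cross-trial rate correlations, latency jitter,
refractory structure, or waveform-level properties. Passing tests therefore
demonstrate that the analysis chain is correct and calibrated for
epoch-mean Poisson-like data, not that it is robust to every pathology of
real recordings.

## Classification and rate extraction

A saccade before target onset — or within 100 ms after it, too early to be a
reaction — marks a break trial: false alarm if the endpoint is a cue
location, abort otherwise; at exactly 100 ms the early rule takes
precedence, so every saccade is classifiable. Completed trials are hits when
an in-window saccade lands on the target location; late saccades count as
no-saccade misses. Reinforcement follows the cue at the target location
(reward on R-hits, punishment on P-misses, never both).

Epoch windows are half-open ([100,400), [400,700), [700,1000) ms), so a
boundary spike is counted exactly once. On completed trials an epoch is
excluded when the target appeared strictly before the window's end (a target
at exactly 1000 ms leaves the third epoch intact). On break trials the
window is truncated at the saccade and excluded when less than 100 ms of it
survives; rates use the effective duration. False-alarm trials are
rate-extracted under the same truncation rule but enter no comparison — the
condition splits use completed trials, and abort-vs-non-abort splits compare
aborts against completed trials. MUA trains sharing a channel with a sorted
unit can be cleaned with `mua_dedup` (drop MUA timestamps within 2 ms of any
SUA timestamp, strict inequality at the boundary).

## Selectivity and population statistics

The ROC index is computed from tie-aware midranks (U/(n_A·n_B)), oriented so
values above 0.5 mean the first-named condition fires more (R-present,
R-contra, P-contra, R/P, abort). Rank-sum p-values are exact for combined
n ≤ 20 without ties and tie-corrected asymptotic otherwise; indices require
≥ 15 trials per distribution, and under-filled cells are omitted (logged),
not erred. Population statistics use standard machinery: OLS with a t-test
on the slope; z-scored multiple regression so the printed-scale standardized
βs are comparable; ANCOVA as the group×slope interaction F-test in a pooled
OLS model (groups = epochs, subjects, or unit kinds at the call site); exact
two-sided binomial tests; χ² without continuity correction, with a Fisher
fallback when an expected cell is below 5; Wilcoxon signed-rank for paired
magnitudes (p = 1 when all differences vanish). Sign agreement restricts to
pairs where both indices are significant, counts same-side-of-0.5 pairs
(an index exactly at 0.5 counts as unmatched), and tests against 0.5; the
per-site sign-agreement score is ±|x−0.5|·|y−0.5| averaged over epochs.
Abort contrasts between trial types are Bonferroni-corrected with family
size 3 (the pairwise contrasts per subject and window).

## Numerical and design choices

* Seeding: one root seed spawns independent child streams for the trial
  sequence and each unit, so adding units never perturbs trials and
  identical configs give byte-identical CSV outputs.
* p-values are clipped into (0, 1]; regression requires n ≥ 3 and a
  non-constant regressor; perfectly collinear multiple-regression designs
  and zero-margin 2×2 tables raise errors rather than returning numbers.
* The abort-selectivity splits use the same 15-trial gate as every other
  comparison; a stricter plotting-only threshold (6 aborts) exists in the
  source material but is not an analysis rule.
* Desk-scale problem sizes: the test suite exercises sessions of ~700–24,000
  scheduled trials and populations of 12–2,000 units, sizes at which every
  calibration check has adequate power while the whole suite completes in a
  few minutes; the acceptance script uses ~22,000 scheduled trials per trial
  type.

## Known limitations

* Truncated-duration abort rates are not identically distributed to
  full-window rates even at equal underlying intensity (for a 10 sp/s unit
  the exact AUC of a 0.1–0.2 s truncated rate against full-window rates is
  0.46–0.49), so the abort-split comparisons reject a true null at ~5.5–7%
  per epoch rather than 5%. This anticonservatism is intrinsic to comparing
  truncated rates with a rank test — the prescribed analysis — and is left
  visible rather than patched; the completed-trial comparisons calibrate at
  4.4–5.6%.
* The generator's outcome draws are conditionally independent across trials;
  real sessions show satiation, fatigue, and streaky aborts. Frequencies
  converge to their parameters, but sequential structure is absent.
* `behavior_tests.csv` reaction-time contrasts use the unpaired rank-sum
  test on hit RTs; no correction is applied across the three trial types.
* One pseudo-session per synthetic "site": cross-session unit identity and
  drift (and the SUA validity-interval bookkeeping real recordings need) are
  out of scope; `SpikeTrain.valid_interval` spans the whole session.
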