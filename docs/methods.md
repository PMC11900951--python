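# Methods

## Problem and scope

Hip registries and long-running clinical studies have collected
patient-reported outcomes on different instruments over time: the modified
Harris Hip Score (mHHS, 0–90, higher = better) in historical collections,
and the Hip disability and Osteoarthritis Outcome Score (HOOS, five 0–100
subscales) or its 12-item short form (HOOS-12) in modern ones.  To compare
such series longitudinally, a *crosswalk* converts a patient-derived (PD)
score on one instrument into the equivalent score on the other.  `promwalk`
implements the full pipeline: questionnaire scoring, crosswalk
construction by two standard observed-score linking methods, validation of
the resulting crosswalk-derived (CWD) scores by mean absolute error (MAE),
and a synthetic total-hip-arthroplasty (THA) recovery cohort that gives
every stage realistic matched data to run on.

## Instrument scoring

**mHHS.** Eight self-reported items with unequal weights: pain
(44/40/30/20/10/0), limp (11/8/5/0), support (11/7/5/3/2/0), walking
distance (11/8/5/2/0), stairs (4/2/1/0), shoes/socks (4/2/0), sitting
(5/3/0) and public transport (1/0).  The public-transport item is retained
in the rubric for data validation but never contributes to the total, so
the maximum is 90 (91 with it).  Domain sums: pain 44, gait 33, activity
(stairs + shoes/socks + sitting) 13.  The rubric ships as an editable CSV;
the code asserts the retained maximum is exactly 90 at load time.  Because
weights are unequal, a visit with any missing retained item has a missing
total — no imputation.

**HOOS.** Forty items coded 0 (best) to 4 (worst) in five subscales
(pain 10, symptoms 5, activities of daily living 17, sport 4, quality of
life 4).  Each subscale is `100 − mean(codes)/4 × 100`, computed from the
answered items when at least half the subscale is answered (the
instrument's customary rule), otherwise missing — never zero.  The overall
HOOS used for total-score crosswalks is the **unweighted mean of the five
subscale scores**; this aggregation is a design choice of this package
(common in practice, but not the only possible reading) and is therefore
stated prominently here.

**HOOS-12.** Extracted from a completed HOOS: three four-item scales
(pain, function, quality of life) scored like HOOS subscales; the total is
their mean.  The exact item subset is a configurable mapping table
(`rubrics/hoos12.csv`); the bundled default uses four pain items, four
function items drawn from the ADL scale, and the full quality-of-life
scale, matching the short form's structure.  Users whose registry
prescribes a specific item list can edit the mapping without touching
code.  Note a known inconsistency in the surrounding literature: the
HOOS-12 "activity" subcategory is sometimes described as 8 questions worth
12 points, which is impossible for 0–4-coded items; this package uses the
4-item function scale for the activity subcategory and documents, rather
than resolves, the discrepancy.

**Subcategories.** Pain/activity subcategory series follow the reporting
convention of the derivation tables: HOOS and HOOS-12 subcategories are
rescaled to 0–100 (100 = best), while mHHS pain is the raw points out of
44 and mHHS activity the raw points out of 13.

## Equating methods

**Percentile ranks.** Each score sample is summarised by the
mid-percentile rank of its distinct observed values,
`100·(#below + ½·#equal)/n`, continuized by linear interpolation between
consecutive distinct scores.  The rank function is anchored at the
instrument range endpoints (offset by half a score unit) so that rank 0
and 100 are reached linearly at the range boundary: bounded instruments
forbid open-ended extrapolation, so source scores outside the observed
data map toward the target range endpoints.  No presmoothing (log-linear
or kernel) of the score distributions is applied; that would be a natural
extension for sparse samples.

**Equipercentile (EQ).** For every integer source score `s` over the full
source range, the crosswalk entry is the target score whose percentile
rank equals the source rank of `s`, obtained by inverting the target rank
function with linear interpolation and clamping to the target range.  The
resulting table is monotone non-decreasing by construction (a
`maximum.accumulate` guard absorbs floating-point wobble only).

**Linear regression (LR).** Ordinary least squares of target on source,
unweighted (no per-time-point weighting), tabulated on the integer source
grid and clamped to the target range.  Slope and intercept are stored at
full precision in the table metadata.  A fitted negative slope is rejected
— a decreasing line cannot be a valid crosswalk.

**Application and rounding.** Integer PD scores are table lookups;
non-integer scores interpolate linearly between adjacent grid entries.
Exported tables carry both an exact column and an integer column rounded
half away from zero; all validation uses the exact values, since rounding
first would add ±0.5 discretisation noise.

**Published equations.** The four derived LR conversions
(`mHHS = 1.0713·HOOS + 2.6526`, `HOOS = 0.7568·mHHS + 8.8474`,
`mHHS = 1.1124·HOOS-12 − 3.1421`, `HOOS-12 = 0.728·mHHS + 13.192`) ship as
ready-made tables.  Where a line leaves the target range (the
HOOS-12 → mHHS line is −3.14 at source 0) the tabulated value clamps to
the range endpoint and application logs a warning.

## Validation

Crosswalk construction is gated on a Spearman rank correlation (average
ranks for ties) of at least 0.3 between the paired PD series; a gate
failure carries the computed coefficient and no table is written.

MAE is the mean of |CWD − PD| over matched pairs, computed on unrounded
CWD values, reported overall, per time point (pre-op, 3, 6, 12 months) and
per pain/activity subcategory.  The overall MAE pools all pairs, so it
equals the count-weighted mean of the per-time-point MAEs; that identity
is asserted in the tests, and either reading (pooled or stratum-averaged)
can be recovered from the report.  An empty stratum is flagged absent, not
zero.  The report also carries the largest absolute CWD−PD difference and
the source score at which it occurred.  Subcategory analysis is
equipercentile-only, because the graded (non-continuous) pain scales make
a linear fit inappropriate there.

**Power analysis.** The minimum number of matched pairs to detect a
correlation of `r_min` uses the t-based critical correlation at the chosen
level together with the bias-corrected Fisher-z approximation
`z_r = atanh(r) + r/(2(n−1))`; the smallest `n` with power at or above
target is found by bisection (power is monotone in `n`).  The analysis is
**one-sided** by default: under this standard approximation, one-sided
testing of r = 0.3 at alpha 0.05 and power 0.8 requires 67 pairs, which is
the published requirement, whereas two-sided gives 85 — that agreement is
the evidence for the one-sided choice, and both variants are exposed.

## Synthetic cohort

The generator emulates the structure of the derivation cohort — 49
patients completing both instruments pre-operatively and at 3, 6 and 12
months, yielding 121 matched visits (35/32/30/24), with matched totals
correlating at Spearman ≈ 0.9 and more variable scores at 3 months —
while inventing nothing patient-specific.

Per patient, a baseline hip-health trait is drawn on an abstract 0–1
scale, `N(0.35, 0.17)` pre-operatively.  Each time point adds a recovery
shift (0 / 0.22 / 0.30 / 0.34) and visit-level noise with standard
deviation 0.03 / 0.12 / 0.06 / 0.05 — the large 3-month term encodes
heterogeneous early recovery and makes 3-month latent (and score) variance
exceed pre-op variance.  At a completed visit both instruments are
answered; each sees the visit trait plus an instrument-specific
discordance deviation (sd 0.055), reflecting that patients answer
differently worded questions inconsistently across forms.  Items convert
the instrument-level trait to codes through equal-width severity bands
jittered per item by Gaussian noise (sd 0.10), so at fixed noise a higher
trait never produces a worse code.  Completion is independent across time
points with probabilities 35/49, 32/49, 30/49, 24/49 (counts matched in
expectation); an exact-counts mode draws exactly 35/32/30/24 completing
patients per time point for tests that need the 121 pairs precisely.

The discordance and item-noise defaults were fixed once by a calibration
run: at 500 patients the pooled matched-total Spearman is 0.90 ± 0.01
across seeds, matching the assumed correlation.  Generation is fully
deterministic given the config (including seed).

**What the generator does not emulate:** clinical covariates, informative
dropout, floor/ceiling response styles, within-patient learning effects,
or the true marginal score distributions of any real population.  Passing
tests on this cohort therefore demonstrate that the pipeline's mechanics
(scoring, equating, validation, reporting) are correct under the assumed
correlation structure — not that any particular MAE value will be observed
on real patients, and the derivation study's table cells are deliberately
not reproduction targets.

## Numerical choices and problem sizes

* Scores are carried as floats end to end; rounding happens only at table
  export and presentation.
* Crosswalk grids cover the full integer instrument range (0–90, 0–100)
  even where unobserved, as published crosswalk appendices do.
* Degenerate inputs are rejected with specific errors: constant score
  series (no invertible distribution, no rank correlation), empty samples,
  out-of-range scores (naming the admissible range), impossible generator
  configs (e.g. a target correlation of 1 with positive noise).
* With all noise disabled, both totals are deterministic monotone step
  functions of the shared trait; the tests assert zero discordant pairs
  and a rank correlation near 1 (exact 1 is unattainable because the two
  instruments quantise the trait differently, producing unmatched ties).
* Test and calibration problem sizes — 121-pair cohorts for structural
  checks, 500 patients for calibration, 600 patients for the
  slope-recovery oracle, 100 random cohorts for monotonicity/range
  properties — were chosen as the smallest sizes at which the checked
  quantities are stable across seeds.

## Known limitations

* Equipercentile equating is unsmoothed; with 121 pairs the tails of the
  crosswalk rest on few observations, exactly as in the derivation study.
* The HOOS-12 item mapping is representative, not registry-certified;
  edit `rubrics/hoos12.csv` to match a specific definition before applying
  HOOS-12 crosswalks to real data.
* No confidence intervals on equated scores are produced.
* Item-response-theory equating, Tobit/quantile regression and Bayesian
  linking are out of scope.
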