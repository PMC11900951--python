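# promwalk

Scoring and multi-directional crosswalks between the modified Harris Hip
Score (mHHS) and the Hip disability and Osteoarthritis Outcome Score
(HOOS / HOOS-12).

## Why

Total-hip-arthroplasty outcomes have been tracked with the mHHS for
decades, while modern joint registries collect the HOOS or its 12-item
short form.  Comparing old and new collections requires a **crosswalk**: a
mapping that converts a patient-derived (PD) score on one instrument into
the equivalent crosswalk-derived (CWD) score on the other.  `promwalk`
implements the whole workflow for clinical researchers and registry
analysts:

* **scoring engines** for mHHS (weighted items, 0–90), HOOS (five 0–100
  subscales of 0–4-coded items) and HOOS-12 (extracted from a completed
  HOOS), with explicit missing-data rules;
* **equipercentile (EQ) equating** — scores with the same mid-percentile
  rank (linearly continuized) in the two distributions are equivalent:
  `target(s) = Q_y(P_x(s))` for every integer source score `s`;
* **linear-regression (LR) equating** — ordinary least squares
  `y = b·x + a`, tabulated and clamped to the target range, plus the four
  published LR conversions (e.g. `HOOS = 0.7568·mHHS + 8.8474`) ready to
  apply;
* **validation** — a Spearman ≥ 0.3 gate before any crosswalk is built,
  and mean absolute error MAE = mean |CWD − PD| overall, per follow-up
  time point and per pain/activity subcategory;
* **power analysis** — the minimum number of matched score pairs to
  detect a correlation (bias-corrected Fisher-z with t-based critical
  correlation);
* a **synthetic THA-recovery cohort generator** producing matched
  item-level mHHS/HOOS responses with a configurable latent recovery
  model, so the whole pipeline runs and is tested without patient data.

## Worked example

```python
import promwalk as pw
from promwalk import io as pio
from promwalk.cohort import exact_fig1_config, generate_cohort

# a synthetic cohort: 49 patients, 121 matched visits (35/32/30/24)
cohort = generate_cohort(exact_fig1_config(seed=20))
scores = pio.score_responses(cohort.responses)
pairs  = pio.matched_pairs_from_scores(scores, pw.MHHS, pw.HOOS)

rho = pw.spearman_gate(pairs)          # raises below 0.3
eq  = pw.equipercentile_crosswalk(pairs)
lr  = pw.linear_regression_crosswalk(pairs)
rep = pw.mae_report(pairs, eq)
```

Printing the key quantities gives:

```
n pairs          : 121
Spearman rho     : 0.939
LR line          : HOOS = 1.0567 * mHHS + 1.5797
EQ MAE overall   : 8.35
EQ MAE preop     : 7.32  (n=35)
EQ MAE 3m        : 10.10  (n=32)
EQ MAE 6m        : 7.74  (n=30)
EQ MAE 12m       : 8.27  (n=24)
largest |CWD-PD| : 34.9 at mHHS = 54
mHHS 70 -> HOOS  : EQ 79.4, LR 75.5, published 61.8
```

Reading this: the matched totals correlate strongly (rho 0.94, well above
the 0.3 gate), so the crosswalk may be built.  Converting each mHHS back
to HOOS through the equipercentile table errs by 8.35 points on average
(on the HOOS 0–100 scale), worst at 3 months where recovery is most
heterogeneous — the characteristic time-point pattern of crosswalk error.
The last line converts a single score three ways; the published line
differs from the two cohort-fitted tables because it was derived from a
different (real) cohort.

The same pipeline is available from the shell:

```sh
promwalk simulate --output resp.csv --seed 20 --exact-counts
promwalk score    --input resp.csv --output scores.csv
promwalk build    --input resp.csv --output-dir crosswalks   # 8 tables
promwalk validate --input resp.csv --crosswalk-dir crosswalks --output report.csv
promwalk convert  --input scores.csv --output conv.csv \
                  --published --source mHHS --target HOOS
promwalk power    # -> 67
```

`promwalk build` writes one CSV per method × direction
(EQ/LR × mHHS↔HOOS, mHHS↔HOOS-12), each with the full integer source
grid, exact and rounded target columns, and header comments recording the
method, direction, pair count and (for LR) the fitted line.

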