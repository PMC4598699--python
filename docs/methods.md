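# Methods

This note records the modelling choices behind `ampmyield`: what each
stage assumes, which parameters matter, and what the synthetic-data
results do and do not demonstrate.

## Traits and units

Nine traits per cow test day: milk, fat, and seven fatty-acid (FA)
traits (SFA, MUFA, UFA, SCFA, MCFA, LCFA, C18:1 *cis*-9). Contents are
concentrations in g/dL of milk, yields are masses per milking or per day
(g; milk in kg). The package uses the convention 1 kg milk ≡ 10 dL, so

```
yield (g) = content (g/dL) × milk (kg) × 10.
```

This reproduces the magnitude relationships seen in routine Holstein
recording (e.g. 4.11 g/dL × 12.79 kg × 10 ≈ 515 g fat per milking).

## Synthetic herd generator (`simulate`)

The generator produces ground truth that routine recording never
observes — both milkings of every cow on every test day — and then
degrades it into the three real observation schemes (mixed 50/50 "S",
alternate single-milking "T", fully observed validation).

Mechanism and defaults:

- **Daily milk**: Wood curve `a·DIM^b·exp(−c·DIM)` per parity class
  {1, 2, 3+} (scales 15.0/17.5/19.0 kg, rise 0.20, decay
  0.0030–0.0038 d⁻¹), multiplied by log-normal cow (SD 0.25) and herd
  (SD 0.10) effects. Any unimodal lactation curve would do for the
  package's purposes; Wood is the field's default.
- **Milking split**: milk at a milking = daily milk × (preceding
  interval / 24 h) + Normal(0, 0.8 kg) noise; the interval before the
  AM milking is Normal(11.5, 1.0) h clipped to [4, 20], and the two
  intervals sum to 24 h. This is the simplest mechanism producing the
  universal finding that the milking after the longer interval carries
  more milk.
- **Fat content**: per-day level = 4.4 g/dL + cow effect (SD 0.60) + a
  mild late-lactation rise, then a dilution term
  `dilution_slope × (milk_session − daily/2)` with slope −0.06 g/dL per
  kg, plus session noise (SD 0.45 g/dL). The dilution sign means the
  bigger milking is the thinner one.
- **FA contents**: mean fractions of fat (SFA 0.66 / UFA 0.34,
  SCFA 0.09 / MCFA 0.51 / LCFA 0.40, MUFA 0.29, C18:1 0.19), with a
  0.05 g/dL seasonal sinusoid moving fat from saturated to unsaturated
  (and medium- to long-chain) groups peaking mid-summer, plus noise.
  UFA and MCFA are computed as complements, so SFA+UFA and
  SCFA+MCFA+LCFA reconstruct total fat exactly by construction.

The numeric defaults were calibrated once against the published
descriptive statistics of large Holstein recording populations (mean
daily milk ≈ 26.4 kg with CV ≈ 0.32, fat 4.3–4.5 ± 0.7 g/dL, AM share
of daily milk ≈ 48%, AM–PM content correlations ≈ 0.55–0.66). The
generator intentionally omits: genetic/pedigree structure, missing
data, within-herd test-day management effects, non-Gaussian content
errors, and any MI→content pathway other than dilution. Passing tests
therefore demonstrate the *machinery* (identities, estimator
consistency, selection behaviour) under realistic magnitudes, not
performance on real cows.

Degenerate inputs: non-positive simulated milk is resampled up to 10
times and then raises; contents are floored at 0.01 g/dL.

## Outlier filter

Records outside mean ± 3 sample SDs on any filtered column are removed,
with means/SDs computed once on the full input (one pass, no
re-filtering of survivors). A zero-SD column imposes no restriction —
the rule is vacuous without variance. Under normality this removes
≈ 0.27% of records per column.

## Decomposition (`decompose`)

The mixing identity `c_mix = 0.5·c_AM + 0.5·c_PM` under-determines the
session contents; alternate-scheme data supply the contrast. Per trait
and session, a through-origin regression of session trait yield on
session milk yield gives slope `b` (g per kg); `b/10` is the implied
session content. Through-origin is used because the expectation model
is `yield = b × milk` with no intercept: no milk, no trait mass.

Two combination rules satisfy the mixing identity exactly:

- **shift** (default): `c_AM = c_mix + d/2`, `c_PM = c_mix − d/2` with
  `d = b_AM/10 − b_PM/10`. It is the unique linear rule using only the
  mixed observation and the `b×milk` expectations that conserves the
  midpoint and reproduces the implied between-session contrast. Note
  the contrast is population-level: the decomposition recovers session
  *means* without bias (tested to 2 Monte-Carlo SEs at n = 10,000) but
  cannot recover cow-specific AM−PM differences.
- **ratio**: allocates the daily trait mass in proportion to the
  predicted session yields `b_s × milk_s`, rescaled to conserve the
  midpoint; record-specific but more sensitive to extreme milk splits.

Expected contents are floored at ε = 0.001 g/dL with the partner
session re-adjusted, so the mixing identity survives clipping; a run
log warning fires if more than 1% of record-traits are clipped.

## Prediction equations (`modelfit`, `presets`)

Terms are covariate products (session milk `milk`, session content `q`)
nested in class crosses of:

- **DIM classes**: 30-day classes up to 300 days, then one open class
  (11 levels) — standard milk-recording practice;
- **parity classes**: {1, 2, 3+};
- **month of test**: 12 calendar months (season/feeding proxy).

A term with class factors gets one design column per occupied subclass
cell (the covariate product inside the cell, zero outside); empty cells
produce no column. Fitting is `numpy.linalg.lstsq` after a greedy
first-come rank screen (tolerance 1e-8 relative to column norm) that
drops aliased columns deterministically — effectively reference-cell
coding with a reproducible reference. `p` counts kept columns including
the intercept. Prediction re-evaluates the stored columns; a class
level absent from training raises (no silent extrapolation), while a
level *combination* whose cell was empty in training contributes zero,
exactly as it did in training.

**Stepwise selection** is forward: each step adds the candidate term
minimizing TEST-set RMSE (`√(SSE/(n−p))`), stopping when the relative
improvement falls below 1e-3 (the named selection procedure in the
source material does not state its entry criterion; validation-RMSE
forward selection is the simplest rule consistent with supplying TEST
and VAL datasets). The VAL dataset is never consulted during selection.
Candidates causing rank collapse (no estimable new column) are skipped.

The 18 preset model forms are expressed in, and parsed from, a
human-readable grammar mirroring how such equations are printed
(`a + b × (qFAT_AM × milk_AM × DIM) + …`).

## Statistics (`evaluate`)

`RMSE = √(SSE/(n−p))` with `p` including the intercept (errors if
`n ≤ p`). `R_y,ŷ` is reported as |Pearson r| × 100 with an explicit
sign flag, since defining it as √R² would silently lose the sign; on
validation data R² is the squared Pearson correlation (not 1−SSE/SST),
keeping `R_y,ŷ` a genuine correlation there too. `σ_ŷ` is the SD of
predictions and must not exceed the SD of observed daily yields; for
training-set least squares with an intercept this holds by the variance
decomposition of the fit. The correlation table reports AM–PM,
AM–daily and PM–daily Pearson correlations per trait for contents and
yields; because both milkings share the cow's milk volume, yield
correlations exceed content correlations.

## Milking-interval analysis (`mi_analysis`)

Five nested least-squares regressions of the session-preceding interval
(hours) on: daily milk; + session milk; + session fat content; + DIM
classes; + parity classes. R²·100 is reported per model with partial
F-tests (α = 0.05) for each added block. Nesting guarantees monotone
R². In the generator's world the daily total is independent of the
interval while the session milk is directly driven by it, so R² jumps
when session milk enters — the mechanism that justifies replacing the
MI with session-level production data. Whether to pool sessions was
open; the package fits each session separately and reports both.

## Pipeline and problem sizes

`run_pipeline` uses a calibration population of 40 herds × 30 cows × 8
visits (~9,600 cow days; a desk-scale stand-in for the ~80,000-record
populations such studies use), an equally sized alternate-scheme
population for the b-regressions, a fully observed TEST population of
690 cow days (the size of a real validation campaign, and comfortably
above the largest preset model's ~400 parameters so `n > p` holds
everywhere), and a VAL population of 2,000 cow days that is — like its
real-world counterpart — itself decomposed from mixed samples with the
calibration b-coefficients. Sub-population seeds derive from the single
run seed; the manifest records row counts and SHA-256 hashes of every
artifact, and reruns are byte-identical.

## Known limitations

- The decomposition's session contrast is constant across records in
  the default strategy; real AM/PM differences vary with cow and stage.
- Preset models with four-way class crosses are over-parameterized for
  very small calibration sets; at the default scale cells hold ~25
  records each, but users fitting smaller datasets should prefer
  stepwise selection or lower-order presets.
- The reported descriptive-statistics tables are reference values for
  magnitude checks only; the package makes no attempt to reproduce
  data-dependent headline correlations of the original populations.
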