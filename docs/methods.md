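# Methods

This note documents the models, rules and numerical choices behind
`paqcal`, in the order the pipeline applies them, and states what the
synthetic-data generator does and does not emulate.

## Accelerometer screening (`paqcal.accel`)

**Day window.** A monitored day is the half-open interval [08:00, 21:00)
— 780 minutes — on the local clock. Restricting to waking hours avoids
diluting %MVPA with sleep time. Epochs at exactly 21:00 are excluded; no
midnight handling is needed.

**Minute aggregation.** The non-wear rule is stated in counts per minute,
so 30-s epoch pairs aligned to clock minutes are summed. An epoch without
a same-minute partner (possible only at ragged window edges) is dropped
from minute aggregation but kept for per-epoch MVPA classification; its
wear status defaults to worn, since non-wear evidence requires a
contiguous minute context that such an epoch lacks. Minutes entirely
absent from a day are treated as zero counts, matching how monitors record
when idle.

**Non-wear.** A maximal run of minutes is non-wear iff it is ≥90 min long
and consists of zero-cpm minutes apart from *interruptions*: maximal
blocks of ≤2 consecutive minutes, each at 1–100 cpm. Any minute above
100 cpm, or a non-zero block longer than 2 minutes, terminates the
candidate run. Interruption blocks are classified on the full minute
sequence, not per candidate window, which makes the rule unambiguous at
run edges (a 3-minute block never contributes a trimmed 2-minute tail to a
neighbouring run). The number of interruptions per bout is not capped —
the rule text bounds each interruption, not their count. The long 90-min
criterion is deliberate: extended sitting during class time should not be
struck as non-wear.

**Cut points.** The MVPA threshold is age-specific. By default the
Freedson-lineage youth MET regression
`METs = 2.757 + 0.0015·cpm − 0.08957·age − 0.000038·cpm·age`
is solved at the ≥4 MET moderate-intensity floor for cpm
(age 10 → ≈1,910 cpm), rounded to the nearest integer count, and halved
for 30-s epochs. A user-supplied age→cpm table overrides the equation.
Monotonicity in age is not assumed; over ages 8–14 the default equation's
threshold in fact rises with age.

**Validity.** A day is valid with ≥546 wear minutes — 70% of the 780-min
window, inclusive at the boundary. (70% of 780 is 546 min = 9.1 h; a
"9.0 hours" restatement would give 540. We treat 546 as primary and leave
the threshold configurable.) A week is valid with ≥4 valid days including
≥3 weekdays and ≥1 weekend day (Saturday/Sunday by calendar date).

**Weekly %MVPA.** Weekday and weekend %MVPA are means of per-valid-day
`100·mvpa/wear` within each stratum. The combined value weights the
strata 5/7 and 2/7 — the week's actual day composition — with an
unweighted mean over valid days available via config, since stratum
reports do not pin down the combination rule. Invalid weeks carry no
combined value.

## PAQ scoring (`paqcal.paq`)

Summary = mean of the checklist score (itself the mean of the checklist
entries) and the remaining item scores: PE, recess (PAQ-C only), lunch,
after school, evening, weekend, and two weekly-pattern items — 9 scored
items for PAQ-C, 8 for PAQ-A. Missing required items are a hard error
naming the item; no pro-rating, as no imputation rule is standard. An
illness item, if present in input, is ignored. Scores are stored at full
precision; the one-decimal convention applies when a score is displayed or
enters the calibration equation.

## Calibration (`paqcal.calibrate`)

**Split.** Week-valid participants are randomly split 70/30; the
calibration size is floor(0.70·n) so 148 participants give 103/45. With
season stratification the fraction holds within each stratum to ±1
(rounding per stratum), so the totals may differ from the unstratified
split by one.

**Model.** OLS of combined %MVPA on sex (coded 1 = male, 2 = female — a
0/1 recode would shift the intercept by the sex coefficient), age in whole
years, and the PAQ score rounded to one decimal. Standard errors use the
unbiased residual variance with df = n − 4; p-values are two-sided from
the t distribution. RMSE = √(SSE/(n−4)), i.e. the standard error of
estimate. R² is the plain (unadjusted) coefficient of determination.
BMI is excluded from the default model (it is rarely obtainable in
school-scale deployments and adds no predictive value here) but can be
examined by passing an extended design to the underlying fit.

**AIC.** Gaussian form `n·ln(SSE/n) + 2k` with k = 5 (four coefficients
plus the error variance). Only differences between models of the same
response are meaningful; the additive constant differs from
log-likelihood-based definitions.

**VIF.** `1/(1 − R²_j)` from regressing each predictor on the other two
with intercept.

**Breusch–Pagan.** Two variants. `bp` is the studentized (Koenker) LM
test: n·R² from regressing squared residuals on the three predictors,
df = 3. `white` augments the auxiliary design with squares and pairwise
products, dropping aliased columns — with 1/2-coded sex, sex² is a linear
combination of the intercept and sex, leaving 8 auxiliary terms (df = 8).
The white variant is the default because the df = 8 reference statistic
for this design arises from exactly that auxiliary form; which auxiliary
specification a given software stack used historically is otherwise
ambiguous, so both are provided. Alias detection is by rank test at
machine precision.

OLS and the `bp` LM statistic are computed via statsmodels; the white
auxiliary design, VIF auxiliary regressions, AIC and RMSE are assembled
explicitly. Tests cross-check coefficients, SEs, VIFs and the non-wear
detector against hand-rolled normal-equation/brute-force oracles.

## Validation (`paqcal.validate`)

Predicted daily %MVPA is the linear combination floored at 0 (percentages
cannot be negative); ages outside 8–14 are allowed with a warning.
Weekly minutes = %MVPA/100 × 5,460, the awake-time base (13 h × 7 d,
i.e. 24 h minus 11 h of sleep/rest). Observed accelerometer minutes use
the same %-based conversion by default so both instruments share one time
base; a raw-minutes mode (mean daily MVPA × 7) is provided, and the two
coincide exactly at full 780-min wear.

Agreement: mean bias (predicted − observed) with SD (n−1 denominator),
95% CI of the bias using the t quantile with n−1 df, limits of agreement
with the fixed 1.96 multiplier — this multiplier combination is the
standard Bland–Altman construction and reproduces both published
intervals — paired t-test, Pearson/Spearman correlations, and the R² and
residual RMSE of the simple regression of observed on predicted (for which
Pearson r = √R² identically).

Guideline classification calls a participant active at ≥420 min/week
(60 min/day) on each instrument, scoring the questionnaire against
accelerometer truth. AUC uses the Mann–Whitney rank formulation over the
continuous predicted minutes (ties contribute ½), which avoids trapezoid
ambiguity and is invariant to monotone transforms; with all observations
in one class it is reported as undefined rather than extrapolated.

## Synthetic cohorts (`paqcal.synthetic`)

The generator's defaults emulate the structure of a 148-youth cohort aged
8–14 (51% male, 55% spring observations):

- **Ages** uniform integers on [8, 14]; **form** PAQ-C through age 11,
  PAQ-A from 12.
- **True PAQ** normal truncated to [1, 5], SD 0.7, with an age gradient
  `mean(age) = 3.2 − 0.111·(age − 9.7)` (≈3.4 at 8, ≈2.7 at 14),
  matching the observed younger ≈3.2 / older ≈2.8 split.
- **True %MVPA** = linear model (defaults: published coefficients) +
  N(0, 2.54) residual, floored at 0. The floor binds for ~1–2% of draws
  at the oldest/least-active corner and attenuates the refitted age slope
  by roughly 0.02 — visible in replicate simulations and accepted as the
  price of a physically valid (non-negative) percentage.
- **Day-to-day variation**: each day's target %MVPA adds N(0, 2.0) noise
  (`pct_mvpa_day_sd`, a free parameter — within-person day-to-day
  variance is not otherwise constrained); set it to 0 for exact
  round-trip fixtures.
- **Wear schedule**: two of seven days carry one 90-min all-zero non-wear
  block (90 min is the minimum the screening rule can detect, so
  scheduled and detected wear agree exactly), giving mean wear
  (5·780 + 2·690)/7 ≈ 754 min/day, matching the observed 754.8 ± 24.7.
- **Traces**: MVPA is placed as contiguous bouts (≤20 min each, evenly
  spaced within wear intervals) whose epoch counts sit strictly above the
  age-specific cut point; other wear minutes draw light activity at
  150–400 cpm — above the 100-cpm allowance ceiling and below every age's
  cut point; the bout epoch count is rounded so realized %MVPA matches the
  day target to within half an epoch.
- **PAQ items**: each response is `clip(round(paq_true + N(0, sd)), 1, 5)`.
  Clipping keeps items on scale but biases the mean slightly toward the
  interior near the scale ends (at paq_true = 5 with sd = 0.5 the expected
  item is ≈4.8).

Everything is seeded: cohort-level draws from the cohort seed, per-
participant trace/item streams from seeds spawned per participant, so
identical seeds give byte-identical datasets.

**What the generator does not emulate:** biomechanically realistic count
distributions or bout structure, spurious wear artifacts, seasonal effects
(the season label is carried but has no effect), reactivity or recall bias
in the questionnaire beyond symmetric item noise, and correlation between
wear compliance and activity level. Passing round-trip tests therefore
demonstrates the correctness of the screening/scoring/fitting machinery
under the model's assumptions, not the field validity of the calibration
equation.

## Problem sizes

The replicate simulation behind `scripts/acceptance.py` and the
recovery test uses 200 cohorts of n = 103 fitted at the cohort level
(~10 s); property suites use 1,000 random 780-minute traces for the
non-wear oracle and 1,000 homoscedastic replicates for the Breusch–Pagan
size check; the end-to-end CLI demo simulates, writes and screens 148
participant-weeks of 30-s epochs (~20 s). These sizes give Monte-Carlo
standard errors comfortably inside the assertion tolerances.

## Known limitations

- The age-specific cut-point equation is a configurable default, not a
  claim about which cut points any particular historical dataset used;
  supply an `age_cpm_table` to reproduce a specific lineage.
- The 546-min valid-day threshold and the 5/7–2/7 combination rule are
  documented choices among defensible alternatives; both are configurable.
- Guideline classification compares weekly totals against 420 min/week;
  it does not implement the stricter every-day-60-min reading.
- No measurement-error correction (attenuation) is applied to the fitted
  slopes; the validation stage quantifies, rather than corrects,
  individual-level disagreement.
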