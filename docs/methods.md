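# Methods

This note records the models implemented in switchscan, the defaults and why
they were chosen, what the simulators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## Experimental design being modeled

Three cohorts of flies: CF (control food), RF (restricted food from
eclosion; chronic dietary restriction), and SF (kept on CF, switched to RF
on the day the CF and RF mortality trajectories are reliably separated —
day 40 by default). Expression is profiled in all three cohorts at the same
post-switch hours {2, 4, 6, 8, 12, 18, 24, 32, 40, 48, 56, 72}; survival is
recorded daily, with flies removed for sampling treated as censored on their
collection day. SF samples before the switch are not generated: the design
profiles only the post-switch window, and CF plays the role of the
pre-switch baseline.

## Expression simulator

Per gene g with baseline `mu_g ~ U(4, 12)` (mimicking the log2 score range
of summarized microarray data), samples are drawn i.i.d. normal with SD
`sigma` around cohort means

* CF: `mu_g`
* RF: `mu_g + delta_g`
* SF at hour t: `mu_g + delta_g * f(t) + offset_g` (offset only for the
  deviating archetype)

where `f` depends on the archetype:

| archetype | f(t) | expected category |
|---|---|---|
| null | 0 (and delta = 0) | V |
| switch_up / switch_down | logistic, midpoint `t0_fast` = 2 h, `tau` = 1 h | I |
| refractory | 0 | II |
| responsive | constant `responsive_level` = 0.5 | III |
| slow_switch | logistic, midpoint `t0_slow` = 36 h, `tau_slow` = 24 h | III |
| deviating | 0, with an SF-only offset ±delta | IV |

Rationale for the shapes: the fast logistic completes (f > 0.98) by 6 h,
matching the observed bulk of switching genes completing within 4–6 hours;
switch_down is a sign flip of delta, not a different f; refractory /
responsive / slow archetypes draw the sign of delta at random (refractory
genes were observed in both directions). The slow archetype is a gentle
drift covering roughly 20 % → 80 % of the CF→RF gap across the 72 h window:
it represents a partial switch that is statistically distinguishable from
both CF and RF over the full time course, hence its expected category is
III. (An earlier shape with `tau_slow` = 12 h left the SF-vs-CF contrast
exactly at the significance margin, making the archetype's ground-truth
category ill-defined — an undesirable property for a generator whose whole
point is known truth.) Genuinely indeterminate behavior — the territory of
categories VI–VIII — arises in simulation from small `delta/sigma`, not from
a dedicated archetype.

Defaults: `delta` = 1 log2 unit, `sigma` = 0.25 (typical residual SD of
replicated, normalized arrays), 3 replicates per (cohort, time) — the
original study does not report its replicate count, so 3 vials is assumed
and configurable. The default archetype mix (88 % null, 1 % / 2 % fast
switch up/down, 3 % refractory, 1 % responsive, 1 % deviating, 4 % slow)
loosely mirrors the relative class sizes reported for a ~14 k-gene array,
including the 2:1 down:up skew of switching genes.

What the simulator does *not* emulate: probe-level array artifacts,
gene–gene correlation, heteroskedastic noise, batch structure, or sex
effects. Passing recovery tests therefore demonstrates correctness of the
statistical logic under the stated generative model, not robustness to
real-array pathologies.

## Survival simulator

Mortality follows the Gompertz law `h_CF(d) = a·exp(b·d)` with defaults
`a` = 0.002 /day, `b` = 0.06 /day, giving a CF median lifespan near 55 days
and ~30 % cumulative mortality by the day-40 switch — a plausible regime for
control-food females and one in which daily deaths around the switch are
plentiful enough to estimate hazards. DR multiplies the hazard by
`dr_hazard_fold` = 0.5 (a 2-fold CF/RF mortality ratio, comfortably above
the 1.5-fold separation criterion). Deaths are daily Bernoulli with
`p = 1 − exp(−h)`; scheduled censoring removes live flies after the day's
deaths are recorded; survivors at the simulation horizon are censored there,
so deaths + censored always equals cohort size.

The SF hazard equals CF before the switch and then moves linearly *in
hazard* to the RF level with weight `w = min(1, (d − switch_day + 1)/(lag + 1))`:
one interpolation step per day on the new diet, reaching RF exactly at
`switch_day + lag` and collapsing to an instant switch at lag 0 without a
special case. Linear-in-hazard (rather than log-hazard) interpolation is the
simplest model consistent with a drop "to the level and trajectory" of RF
within ~3 days.

## Demography estimators

* Life tables are 1-based day-indexed; censoring on day d removes flies
  after day-d deaths (sampled flies were alive when collected).
* Hazard: `ĥ(d) = −ln(1 − D/N)` with D, N summed over a centered window;
  NaN where N = 0 or D = N. The default window of 5 days pools roughly 200
  deaths per cohort near the switch at n = 3000 (SE of a log hazard ratio
  ≈ 0.1) while spanning only ±2 days around the 3-day SF transition; wider
  windows smear the transition into the post-convergence days, narrower ones
  are too noisy.
* Separation/convergence detection use consecutive-day run rules (defaults
  k = 3 for separation at fold 1.5, k = 2 for convergence at tolerance 25 %)
  because single-day ratio excursions at daily death counts of a few dozen
  are common; the original criterion ("consistent" fold difference) names no
  rule, so both k and the window are exposed parameters.
* The log-rank test is the standard O/E/V chi-square with hypergeometric
  variance; maximum lifespan is the mean death day of the top
  `ceil(0.10 · n_deaths)` deaths, censored flies excluded.

## Differential expression and categorization

* Pairing unit: replicates are averaged within (cohort, time) before
  differencing, giving one difference per shared time point (12 by default).
  Replicate-level pairing across cohorts is undefined (replicates are
  unordered vials), so time-level pairing is the default and only mode.
* Pooled FDR: one BH step-up over all genes × all three comparisons jointly,
  i.e. the literal "pooled p values from all tests and comparisons". This
  makes per-comparison significance depend on the global p-value mixture,
  which is intentional.
* Zero-variance conventions: identical paired series give t = 0, p = 1; a
  constant non-zero difference gives t = ±∞, p = 0 and is flagged in the
  `zero_variance` column.
* Categories VI–VIII: the original criteria live in unpublished
  supplementary material, so the implemented rules are explicit substitutes:
  VIII = pooled within-(cohort, time) replicate SD above 3× the gene median
  (too variable); otherwise the SF late-time mean (last 3 sampled hours) is
  placed in the CF→RF gap — within 25 % of CF → VI (non-responding), farther
  → VII (slow/partial). All thresholds are configurable; when no expression
  matrix is supplied the fallback routing is VI for diet-dependent and VIII
  for diet-independent indeterminate patterns.
* Category IV requires significance of SF-vs-CF only; the SF-vs-RF state is
  recorded but not required.
* Switch-completion time: earliest sampled hour from which the SF time-mean
  stays within `1 − completion_fraction` (default 10 %) of the RF level; the
  completion fraction is an assumption (the original "complete switch within
  6–8 hours" curation criterion is not formalized in the text). Degenerate
  CF≈RF gaps yield no switch time, with a warning.
* `detect_convergence` takes only the SF and RF hazard series: the stated
  convergence criterion compares SF to RF alone, so a CF argument would be
  inert and is omitted.

## Enrichment and concordance

The universe defaults to all genes on the measured matrix (the array is the
implicit universe); an annotated-only universe is available by flag. Only
upper-tail (over-representation) tests are performed, BH-corrected within
each (category, direction) family, mirroring per-table corrections.
Concordance percentages are rounded to the nearest integer, matching the
reporting style of the numbers they are compared against; genes present in
only one study are excluded from the concordance counts but visible in the
2×2 marginals.

## Problem sizes used in validation

The test suite and acceptance script use: 2 000 genes × 12 time points × 3
replicates at delta = 2, sigma = 0.25 for archetype recovery; 200 all-null
replicates of 500 genes for FDR control; 50 replicate demographies of 3 000
flies per cohort for mortality-switch detection. These sizes give recovery
and detection-rate estimates with standard errors of a few percent while
keeping a full validation run in the minutes range on one CPU.

## Known limitations

* The estimator surface (`SwitchCategorizer`, `QuantileNormalizer`) covers
  the transform/classify-shaped steps; simulation, demography and the set
  statistics are plain functions by design.
* No empirical-Bayes variance moderation: at 12 paired differences the
  t-test is adequate, but very small time grids would benefit from
  shrinkage.
* The survival simulator has no vial-level clustering of deaths, so
  real-data overdispersion will widen hazard-ratio noise relative to the
  simulated setting.
* Quantile normalization assumes columns share a common distribution; it is
  provided for completeness and is off by default in the pipeline, since the
  generator already produces normalized-scale scores.
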