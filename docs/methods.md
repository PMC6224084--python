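# Methods

`bbqrisk` estimates the extra lifetime risk of cancer attributable to
benzo[a]pyrene (BaP) in barbecued meat and fish, for an adult national
population and for six sex × bodyweight subgroups, by chaining five models:
an event-based dietary exposure simulation, censored distribution fitting
for the inputs, an uncertain human-to-animal dose conversion, a two-stage
quantal dose-response model, and a two-dimensional (second-order) Monte
Carlo that keeps inter-individual **variability** strictly separated from
scientific **uncertainty**.

## Exposure model

The yearly BaP intake rate of individual *i* (µg/kg bodyweight/year) is

    y_i = (1 / w_i) · Σ_{b=1..B_i} Σ_{k=1..K_ib} x_ibk · c_ibk

- `B_i` — annual barbecue events, drawn from four scenarios
  {0, 9, 25, 63} events/year with population fractions
  (0.040, 0.265, 0.455, 0.240).
- `K_ib ∈ {1, 2}` — meat types per event, drawn from a meal-composition
  table of (types, partial-consumption shares, probability) rows.
- `x_ibk` — amount of type *k* (kg): one gamma-distributed total amount per
  event (sex × weight-class specific, in g/meal; converted to kg only where
  `x·c` is formed) split by the composition shares. Meat types and shares
  are drawn independently of weight class; only the total amount is
  class-specific.
- `c_ibk` — BaP concentration (µg/kg), i.i.d. per event and type from the
  type's lognormal (two-component lognormal mixture for minced beef).
  Within-event correlation between types is not modelled; the draw is a
  plain i.i.d. sample (simplest assumption; the sampler is a single code
  path where a shared-event multiplier could be added).
- `w_i` — bodyweight (kg) from the no-intercept regression
  `w = β₁·sex + β₂·age + β₃·ln(age) + ε`, with
  β = (−14.476, −0.829, 36.406), residual SD 13.265, sex coded 1 = male,
  2 = female (the coding under which these coefficients give plausible
  predictions, ≈87 kg vs ≈72 kg at age 40). Draws ≤ 30 kg are rejected and
  resampled — the normal error term can otherwise produce non-physical
  adult weights. Weights are rounded to integer kg before banding into
  sex-specific classes (men ≤76 | 77–87 | ≥88; women ≤62 | 63–72 | ≥73,
  class medians 71/82/96 and 58/67/80 kg), so the integer band edges are
  exhaustive.

The population model simulates 10,000 individuals (uniform ages 16–75,
balanced sexes by default; the demographic table is configurable). The
subgroup model fixes bodyweight at the class median and sweeps
B = 1..100 with 5,000 replicates per cell. Subgroup replicates accumulate
their own event stream across the B grid (per-replicate cumulative sums):
each fixed-B marginal distribution is unchanged, every replicate's exposure
is monotone in B by construction, and the grid costs one pass of event
draws instead of one per B. Replicate *r* also shares its sensitivity
quantile across the six cells. Both are common-random-number choices that
sharpen subgroup contrasts without biasing any marginal.

## Distribution fitting

- **Gamma consumption** — ML in the shape/rate parameterisation
  (`scipy.stats.gamma.fit` with location pinned at 0); the fitted mean
  equals the sample mean up to optimiser tolerance.
- **Censored lognormal** — many concentration samples fall below the
  sample-specific limit of detection (LOD). Apparent zeros are treated as
  left-censored, never substituted (no LOD/2): detected records contribute
  the lognormal density, censored records the CDF at their own LOD.
  Multistart Nelder–Mead from moment estimates of the detected values; with
  0 % censoring the result matches the closed-form MLE of the logs to 1e-6.
  An all-censored sample is rejected (the likelihood is unbounded in the
  log-mean).
- **Censored two-component mixture (MAP-EM)** — for minced beef a single
  lognormal is inadequate. The EM E-step uses exact truncated-normal
  moments for the latent log-value of each censored record; the M-step is
  conditional maximisation (means given variances, then variances), so the
  penalised log-posterior is non-decreasing — asserted in the tests.
  Priors are configurable and weakly informative by default: Beta(1,1) on
  the weight, Normal(0, 10²) on each log-mean, and a weak inverse-gamma
  (shape 1, scale 0.5) on each squared log-SD. The inverse-gamma (rather
  than, say, a half-normal on the SD) keeps every update in closed form and
  preserves the EM ascent guarantee. Components are returned ordered by
  log-mean, which makes the fit invariant to label-permuted initialisation.
- **Bodyweight regression** — ordinary least squares without intercept
  (three columns, solved directly by `lstsq`); residual standard error with
  n − 3 degrees of freedom. The residuals of such data are known to be
  somewhat asymmetric; that caveat is noted, not modelled.

## Dose conversion and dose response

The animal-equivalent dose of individual *i* is

    d_i = y_i · CF_intra,i · CF_inter,allometric · CF_inter,TKTD

- `CF_intra,i = GSD^z_i` with geometric mean 1: z_i is a fixed
  standard-normal sensitivity quantile per individual (variability), while
  the GSD itself is uncertain: GSD_u = 3.6^√(df/χ²) with χ² ~ chi-squared
  (df = 21), the standard treatment of an uncertain log-scale SD. The
  central draw χ² = df reproduces GSD = 3.6 exactly. Factoring CF_intra
  into (fixed quantile) × (uncertain GSD) is what lets the individual's
  sensitivity rank stay identical across uncertainty iterations.
- `CF_inter,allometric = (bw_human / bw_animal)^(1−AP)`, AP ~
  Normal(0.7, 0.033²); bw_human is 76 kg for the population and the class
  median for subgroups; bw_animal = 0.03 kg (mouse).
- `CF_inter,TKTD` ~ lognormal(GM 1, GSD 2).

Extra lifetime risk uses the two-stage quantal model

    ER(d) = 1 − exp(−(d/b) − c·(d/b)²)

with potency b and shape c ≥ 0 (observed incidence p = a + (1−a)·ER with
background a pinned at the control rate during fitting). The published form
of this equation omits the minus sign on the exponent, which would give
negative risks; the standard negative-exponent form is implemented, and
with the central parameters (b = 29 089.6, c = 8.925) it reproduces the
reported risk magnitude (~1e-5–1e-4 at the median exposure).

**Units.** The yearly human exposure enters ER directly (no /365). That is
the only convention under which the central (b, c) reproduce the reported
median risk; the per-day conversion is applied solely in the
margin-of-exposure and linear-extrapolation comparators, which are defined
per day (MOE = BMDL₁₀/dose; linear risk = 0.10·dose/BMDL₁₀).

(b, c) uncertainty comes either from a parametric bootstrap of the tumour
study (counts resampled from the fitted binomials and refit, preserving the
b–c correlation), or from published three-percentile summaries
(2.5th, median, 97.5th) resampled with a **two-piece lognormal**: a
standard-normal z scaled by a lower sigma when negative and an upper sigma
when positive, so all three printed percentiles are matched exactly. From
percentile summaries b and c are drawn independently — their correlation is
not published. This is a flagged approximation: it inflates the upper tail
of the risk uncertainty (the printed interval upper end, 7.0e-4, implies
strongly positively correlated b and c, under which extreme c draws are
accompanied by extreme b and largely cancel). Consequently the
97.5th-percentile column of the events-to-exceed table saturates at 1–2
events, where the reported values are 3–5; the median column is unaffected.

BMD₁₀ solves ER(d) = 0.10 in closed form (quadratic in d/b); BMDL₁₀ is the
5th percentile of per-draw BMDs.

## Two-dimensional Monte Carlo

The variability dimension (individuals: y_i, z_i) is frozen first; the
uncertainty dimension then draws, per iteration u, one tuple
(GSD_u, AP_u, TKTD_u, b_u, c_u) and maps every individual through
dose → ER. Row u of the resulting surface is one internally consistent
"possible world"; its average over individuals is one draw of the
population mean risk, and the distribution of those averages over u is the
uncertainty of the mean risk, summarised by its median and 2.5/97.5
percentiles. Defaults: 10,000 × 2,000 (population), 5,000 × 1,000
(subgroups), both configurable.

The subgroup model reuses one shared uncertainty stream for all six cells,
and runs with the same master seed share the stream between the population
and subgroup models (the named-substream RNG guarantees this), so the
events-to-exceed comparison — smallest B at which a subgroup's median mean
risk exceeds the median population mean risk — is not blurred by
independent threshold noise. Seeding is by named substreams spawned from
one master seed (demographics, frequency, sensitivity, exposure,
uncertainty, bootstrap, …), so changing one stage's iteration count never
perturbs another stage's draws.

## Synthetic data and calibration

The original surveys (national dietary records, concentration monitoring,
household barbecue frequencies, the mouse coal-tar study) are not publicly
deposited. The `synthetic` module generates datasets of the same shape from
known ground truth, which serves two roles: recovery targets for every
fitting routine, and shipped default parameters for the simulation.

The defaults were fixed once, at design time, against published summary
statistics and then frozen:

- gamma means per sex × class (175/185.3/196.9 g men, 120/126.6/136.1 g
  women, shape 2.5) encode the reported per-event exposure ordering — low
  bodyweight ≈9 % above medium and ≈20–22 % above high for both sexes;
- concentration geometric means (0.28–1.15 µg/kg across types, log-SD 1.3,
  mixture for minced beef) were scaled by a single global factor so the
  simulated population median and 95th-percentile yearly exposure match the
  reported 0.07 and 0.29 µg/kg bw (achieved: 0.072 / 0.275);
- the meal-composition table (80 % single-type meals, five two-type
  combinations) and the uniform-age, balanced-sex demographics are plain
  placeholders — the true tables are unpublished.

What passing tests therefore show: the machinery reproduces the reported
population-level quantities under inputs constrained to the published
marginals. What they do not show: fidelity to the unpublished survey
microstructure (age-consumption correlation, true meat-type mix, real LOD
spectrum), to which subgroup contrasts are mildly sensitive.

## Numerical choices and limitations

- Optimisers: Nelder–Mead with tight tolerances and multistart for the
  censored lognormal and two-stage fits; the bootstrap warm-starts each
  refit from the full-data estimate. Non-convergence raises; the mixture EM
  attaches its best-so-far estimate to the error.
- ER saturates to exactly 1.0 in floating point once the exponent exceeds
  ~36; the mathematical bound ER < 1 is asserted only in the representable
  regime.
- The headline acceptance checks run scaled down (2,000 × 200–300); at
  these sizes the median of the mean risk is reproducible to within a few
  tens of percent across seeds, comfortably inside the factor-of-two
  bracket used by the tests. The analysis scripts default to the full
  published sizes (~1 min total).
- Lifetime risk treats the simulated yearly exposure as
  lifetime-representative; no longitudinal diet change, no aggregation with
  non-barbecue BaP sources, no other PAHs or heterocyclic amines — all
  out of scope, mirroring the scope of the assessment this package
  implements.
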