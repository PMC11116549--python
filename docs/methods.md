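# Methods

## Causal model and assumptions

The estimand is the set of counterfactual five-year survival probabilities
`E(Y^{a=i})` for four point treatments (no drug, Memantine, Donepezil,
combined), identified under consistency, conditional exchangeability given
the measured confounders `L`, and positivity. `L` collects four
categorical demographics (age group at diagnosis, sex, race, marital
status, each with an explicit "Unknown" level) and six binary comorbidity
flags (cerebral infarction, diabetes, overweight/obesity, hypertensive
diseases, other heart disease, acute/chronic kidney disease). Treatment
switchers are excluded upstream, so treatment is a single time-fixed
four-level variable; no time-varying methods are used.

All categoricals are reference-coded (first documented level dropped), so
`L` contributes 20 columns plus an intercept at the default schema.

### Estimators

* IP weighting: baseline-category multinomial logit for `P(A=i|L)`;
  Horvitz–Thompson means with *unstabilized* weights `1/π̂ᵢ(L)`. HT is
  deliberately not normalized, so finite-sample values can leave [0, 1];
  they are reported unclipped with a warning, because clipping would break
  the doubly robust algebra built on top.
* Standardization: logistic outcome model with confounder main effects,
  three treatment indicators and all treatment×confounder interaction
  products (interactions on by default — the only coding that lets the
  outcome surface differ freely by arm). The g-formula mean averages the
  arm-`i` prediction over all subjects.
* Doubly robust (AIPW): the standardized prediction plus the IP-weighted
  residual correction, reducing exactly to standardization when residuals
  vanish and to HT when `b̂ ≡ 0` (both covered by exact tests).

Contrasts take the combined strategy against each comparator: risk
differences, relative percent increases (comparator mean as denominator),
risk ratios, and the additive drug–drug interaction
`DDI = E(Y^{a=3}) − E(Y^{a=2}) − E(Y^{a=1}) + E(Y^{a=0})`.

### Inference

Nonparametric bootstrap: patients resampled with replacement to the
original n; both nuisance models refitted per replicate (warm-started at
the original-data coefficients); eight statistics recorded (four DR means,
three RDs, DDI). Intervals are empirical percentiles with linear
interpolation between order statistics (the numpy default quantile rule;
no rule is canonical, so one is fixed and documented). Bonferroni
adjustment divides the two-sided 5% error by the family size: 4 for the
means family (levels 0.00625 / 0.99375), 3 for the risk differences, and 1
for the DDI, which keeps a naive interval. Replicates where an arm empties
or a fit fails are excluded and reported, never redrawn (redrawing would
bias the bootstrap distribution); more than 10% failures aborts. At the
default cohort scale roughly 1–3% of replicates fail, essentially always
because a resample misses one of the very rare demographic levels
(e.g. the 5-patient "Unknown" sex level).

### Sensitivity and extrapolation

E-values use the standard transform `RR + sqrt(RR(RR−1))` for `RR ≥ 1`,
inverting protective ratios first; the CI E-value transforms the bound
closer to the null and is 1 when the interval crosses 1. (The additive
form with `1 − RR` under the square root that sometimes appears in print
is imaginary for `RR > 1`; the implemented transform is the one that
reproduces the published E-value tables.) Lives-extended extrapolation
multiplies population size × comparator-group share × risk difference,
rounds each group to the nearest thousand before summing, and scales the
*unrounded* total for future-population projections — the convention that
reproduces the published 157k/98k/48k → 303k and ~652k figures.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not visit-level
EHR reality: covariates drawn independently from configurable categorical
marginals (defaults equal the published cohort tables), treatment from a
multinomial-logit law, outcome from a logistic law, follow-up fixed at 5
years for survivors and uniform(0, 5] for deaths. The death-time law is
plumbing for person-year rate code only — nothing in the analysis depends
on it, and crude mortality rates from synthetic data are therefore not
comparable to published rates.

Confounding runs through a single latent severity direction with
arm-specific loadings (0.5, −0.4, 0.8) on assignment and unit loading on
survival. Per-arm intercepts are then calibrated by iterative proportional
fitting over the enumerated covariate support so that expected arm shares
equal the published 48.30 / 11.35 / 30.70 / 9.66% exactly, and per-arm
outcome offsets by scalar Newton so the true counterfactual means equal
0.780 / 0.781 / 0.765 / 0.830 exactly. Treatment×covariate interaction
coefficients are zero in the default law (the analyst model that includes
them is still correctly specified, just overparameterized). Overall
survival lands near the published 78% automatically.

True counterfactuals are computed exactly by enumerating the finite
covariate support (21,504 cells at the default schema) and averaging the
true `bᵢ(L)`; a Monte Carlo path with reported standard error exists for
specs with large or continuous-extended support.

**Misspecification scenarios.** The hidden transform is the product of
two comorbidity flags — a function of *observed* fields that analyst
models (which never include flag×flag interactions) cannot represent.
Scenario `propensity_wrong` adds it to the true assignment logits,
`outcome_wrong` to the true outcome logit, `both_wrong` to both. The
reduced benchmark design used for the double-robustness Monte Carlo (age,
sex, two flags at 45% / 55% prevalence so the product is common, hidden
coefficients (0.8, −0.6, 1.0) on assignment and 1.6 on outcome) is
calibrated so the singly robust estimator matching the broken model shows
bias far outside Monte Carlo noise while weights stay bounded; with the
published-table marginals the comorbidity products are too rare for a
sharp benchmark.

What passing tests show: the estimators do what the theory promises under
the assumed structure (independent covariates, correctly enumerable
support, point treatment, no unmeasured confounding unless injected). What
they cannot show: robustness to correlated covariates, informative
censoring, treatment switching, or real-data positivity problems.

## Numerical choices

* Both MLEs are full Newton–Raphson with step-halving on the
  log-likelihood; convergence at max |score| < 1e-8 or max parameter change
  < 1e-10, max 100 iterations. Tiny relative Levenberg damping
  (1e-10 × max diagonal) and a per-iteration step cap of 10 keep iterations
  stable when a saturated cell drives a fitted probability to 0/1; neither
  changes the optimum. Softmax and log-likelihoods use max-subtraction /
  `logaddexp` for overflow safety.
* Separation (still-diverging coefficients past |β| = 40 at the iteration
  cap) raises an error advising the optional ridge fallback (small L2 on
  non-intercept terms, off by default).
* The outcome design drops interaction columns that are all-zero or
  collinear in the sample (empty treatment×level cells), fixing their
  coefficients at 0 — those interactions are simply not estimable; the
  selection is greedy in column order so main effects always win over
  interaction duplicates. The propensity design is *not* auto-repaired:
  rank deficiency there is an error, and inside the bootstrap such
  replicates are recorded as failures.
* Positivity: any fitted own-arm probability of exactly 0 is an error; a
  floor of 1e-3 triggers a warning, with no trimming by default.
* SMD balance: weighted means/SDs in the pseudo-population, pooled-SD
  denominator `sqrt((v₁+v₂)/2)`; multi-level categoricals summarized by
  the maximum-|SMD| indicator column so the table is one row per covariate
  (10 rows × 6 treatment pairs). Zero pooled SD yields 0 when means agree,
  NaN otherwise.
* "Switcher" is the strictest reading: more than one distinct regimen
  label over follow-up, so monotherapy followed by the combination counts
  as a switch. The minimum-share filter (0.5%) is evaluated on the
  post-switcher-removal cohort. Date windows are inclusive on both ends.
  Table percents use two-decimal half-up rounding.

## Monte Carlo problem sizes

Chosen to make each check sharp at desk scale on one CPU:

* Double robustness: n = 50,000 per replicate on the reduced benchmark
  design; 200 replicates total (40 well-specified, 80 per single-broken
  scenario). Bias is assessed per arm as mean error over replicates in
  units of its Monte Carlo standard error (|z| < 3 unbiased, |z| > 3
  biased-by-design).
* Bootstrap coverage: n = 1,200 on a two-confounder design, B = 500,
  200 outer replications of the 95% interval for the no-drug risk
  difference. n = 1,200 is the smallest size at which the smallest arm
  (~115 patients) keeps percentile intervals in their asymptotic regime;
  pilot runs at n = 600 showed genuine small-sample undercoverage (~85%),
  which is a property of percentile bootstraps at that size, not of the
  implementation.
* Default bootstrap B is configurable; analyses here use 300–500, and the
  full 10,000 of a production run is a flag away.

## Known limitations

* Covariates are generated independently; real comorbidity co-occurrence
  is not modelled (a correlation extension would slot into the generator's
  marginal-sampling step).
* The generator emits one regimen label per patient, so filter-chain tests
  construct switchers explicitly; no visit-level trajectories exist.
* HT means are unstabilized; with near-positivity violations they are
  noisy by design, which the DR correction inherits in smaller samples.
* The E-value treats unmeasured confounding only; selection bias and
  measurement error are out of scope.
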