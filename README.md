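# drcausal

Doubly robust causal inference for the effect of Alzheimer's-disease
treatment strategies on five-year survival.

Observational EHR cohorts confound treatment choice with prognosis:
patients put on Memantine, Donepezil, or both differ systematically from
untreated patients. This package implements the full estimation pipeline
for comparing four treatment strategies — 0 = no drug, 1 = Memantine
monotherapy, 2 = Donepezil monotherapy, 3 = combined — on a binary
five-year survival outcome, for epidemiologists and biostatisticians who
want each stage testable against known ground truth.

## The estimators

With outcome `Y`, treatment `A ∈ {0,1,2,3}` and confounders `L`, the target
is the set of counterfactual means `E(Y^{a=i})`. Three estimators are
provided:

* **IP weighting.** A multinomial logit
  `log[P(A=i|L)/P(A=0|L)] = βᵢᵀL` gives assignment probabilities
  `π̂ᵢ(L)`; the Horvitz–Thompson estimator averages `I{A=i}·Y/π̂ᵢ(L)`.
* **Standardization (plug-in g-formula).** A logistic outcome model with
  treatment main effects and treatment×confounder interactions gives
  `b̂ᵢ(L) = P̂(Y=1|A=i,L)`, averaged over the empirical confounder
  distribution.
* **Doubly robust (AIPW).** The combination
  `(1/n) Σₖ [ b̂ᵢ(Lₖ) + I{Aₖ=i}/π̂ᵢ(Lₖ) · (Yₖ − b̂ᵢ(Lₖ)) ]`,
  consistent when *either* model is correctly specified.

Derived quantities: risk differences `RDₛ = E(Y^{a=3}) − E(Y^{a=s})`, risk
ratios, the additive drug–drug interaction
`DDI = E(Y^{a=3}) − E(Y^{a=2}) − E(Y^{a=1}) + E(Y^{a=0})`, nonparametric
bootstrap percentile intervals (naive and Bonferroni-adjusted), E-value
sensitivity analysis (`E = RR + √(RR(RR−1))`), and population-level
lives-extended extrapolation.

Because real EHR data of this kind is licensed, the package ships a
synthetic cohort generator (`drcausal.cohort`) whose default generating law
matches the study cohort's published marginals, treatment shares
(48.30 / 11.35 / 30.70 / 9.66%) and counterfactual survival
(0.780, 0.781, 0.765, 0.830) — with the true counterfactuals computable
exactly by enumerating the covariate support. Misspecification scenarios
deliberately break the treatment or outcome model to exercise the double
robustness property.

## Worked example

```python
import drcausal as dc

spec = dc.published_cohort_spec(n_patients=12_744, seed=1)
cohort = dc.generate_cohort(spec)
cohort, report = dc.apply_study_filters(cohort)
matrix = dc.build_analysis_matrix(cohort, spec.schema)
cf, eff = dc.estimate_all(matrix)
print(cf.means_dr.round(3))   # [0.779 0.769 0.776 0.816]
print(eff.rds.round(3))       # [0.037 0.047 0.04 ]
print(round(eff.ddi, 3))      # 0.05
```

The four doubly robust means are the estimated five-year survival
probabilities had everyone received each strategy; the risk differences
say the combined strategy raises survival by 4–5 percentage points over
each comparator in this draw, and the positive DDI means the combination
helps more than the two monotherapy effects added together. The
generating truth here is (0.780, 0.781, 0.765, 0.830) with DDI 0.064, so
each estimate is within sampling error of its target.

The same pipeline as a sequence of analysis drivers (each writes its
tables under `results/`):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_cohort_descriptives.py
python analysis/03_estimate_effects.py
python analysis/04_bootstrap_ci.py --reps 500 --seed 1
python analysis/05_sensitivity_extrapolation.py
```

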