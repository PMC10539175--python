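# Methods

## The scientific question

After a haematopoietic cell transplant, granulocyte recovery is the
earliest and least-confounded marker of bone marrow recovery. Two linked
questions drive this package's design: (1) is there a *threshold* CD34⁺
cell dose below which recovery cannot occur, or does the recovery hazard
rise continuously from zero dose; and (2) should dose be normalised by
body weight, as is conventional, or by recipient blood volume, which
tracks lean body mass. Distinguishing a threshold from a continuous
dose–response requires estimating the *shape* of the hazard-versus-dose
curve, not comparing discretised dose groups — hence the penalised-spline
Cox model at the package's core.

## Cohort simulator

The clinical cohort the analysis targets (619 consecutive single-unit
umbilical cord blood transplants for acute leukaemia) is not publicly
available, so all testing runs on synthetic cohorts that emulate its
printed summary structure.

**Dose distribution.** Per-kg CD34⁺ dose is log-normal with
μ = 0.773, σ = 0.781 on the natural-log scale of 10⁵ cells/kg. These two
parameters are the closed-form fit to the published 5th and 25th
percentiles (0.60 and 1.28 × 10⁵/kg); the implied 10th percentile
(0.80 vs printed 0.83) and the expected minimum at n = 619 (≈ 0.18 vs
printed 0.17) then follow without further tuning.

**Demographics.** Sex is balanced; half of recipients are adults
(age > 16), matching the cohort's "almost one-half" adult fraction.
Adult weight is normal (62 ± 11 kg); paediatric weight follows an
age-linear mean (8 + 2.5·age kg) with multiplicative noise. Lean body
mass is a sex-specific fraction of weight (0.80 M / 0.72 F, SD 0.05,
clipped to [0.45, 0.95]), producing a realistic spread of LBM/BW ratios
so the "extreme ratio" stratification is exercised; blood volume is
80 mL per kg LBM.

**Outcomes.** Recovery time follows the proportional-hazards model
h(t|d) = h₀(t)·r(d), sampled by inverse transform: T = scale·(E/r)^(1/shape)
with E ~ Exp(1). The baseline is Weibull(shape 4, scale 20.82 days),
giving a median recovery of ≈ 19 days at relative hazard 1 — a typical
cord blood engraftment median. No baseline distribution is published for
the target cohort; only the dose→hazard mapping matters for the
downstream estimators, so this choice affects timing scale, not any
tested property. Death before recovery is an independent exponential
competing event at 8.5 × 10⁻⁴/day, calibrated so that ≈ 10 of 619
recipients die before recovery (reproducing the cohort's 619 → 609
analysis-set drop). Administrative censoring is at day 60. Observed event
times are rounded up to whole days, which intentionally produces the
heavy ties of real engraftment data.

**Scenario curves.** The generative dose→relative-hazard curve r(d) is
explicit and pluggable:

- `threshold`: r = 0 below d₀, constant above — the curve a threshold
  dose would produce;
- `plateau`: a linear ramp from `low_level` (default 0.5) to
  `high_level` (default 1.5) at breakpoint d₀ (default 3 × 10⁵/kg when
  applied per body weight) — the published no-threshold shape (hazard
  ≈ 0.5 at very low dose, saturating at ≈ 1.5). Only the plateau levels
  and breakpoints are published; the linear ramp between them is this
  package's minimal continuous, non-decreasing interpolation;
- `linear`: log-linear in dose, for slope-recovery tests;
- `flat`: r ≡ 1, the null.

At dose exactly zero every curve returns 0 (nothing to engraft). The
scenario applies to one named metric (per-BW by default); the other two
metrics then carry correlated but noisier signal through the shared
weight and lean-mass variables, mirroring the metric comparison the
concordance table makes.

**What the simulator does not emulate.** No relapse or survival
processes, no immune reconstitution, no covariate-confounded dose
assignment (dose is independent of everything but weight), and no daily
granulocyte counts — recovery is a latent event time, since the clinical
definition of sustained granulocyte recovery is not modelled numerically.
Passing tests therefore demonstrate estimator correctness and calibration
under the stated generative structure, not robustness to the confounding
present in real registry data.

## Dose metrics

Doses are reported on the published scales: 10⁵ cells/kg and 10⁷ cells/L.
Blood volume defaults to a constant 80 mL per kg of lean body mass — the
LBM-proportionality that motivates per-BV dosing — with the Nadler
sex-specific height–weight formula as an alternative; the estimator used
is recorded in the output. The "extreme" LBM/BW stratum is strictly below
the cohort's 15th or strictly above its 85th percentile of the ratio
(at n = 619 with distinct ratios this yields 186 extreme / 433 normal).

Poisson HSC-sampling noise: with λ = CD34⁺ count × (HSC per CD34⁺ cell)
expected stem cells, the package reports the coefficient of variation
100/√λ and the three-sigma relative width 300/√λ, in percent. The
three-sigma width is the interpretation consistent with the worked
example of a 40 × 10⁵-cell graft at 1 HSC per 5000 having "10 percent"
variation (300/√800 = 10.6%).

## Penalised-spline Cox model

**Likelihood.** Cox partial likelihood with the Efron tie correction
(event days are heavily tied). Deaths before recovery and censored
recipients contribute as censored at their event time; the hazard
analyses therefore use all rows, while the day-21 logistic endpoint
excludes deaths.

**Basis.** Restricted cubic spline in log₂(dose): truncated-power cubic
basis with boundary corrections, scaled by (t_K − t₁)², exactly linear
outside the boundary knots. Default 5 knots at Harrell's percentile
positions (5/27.5/50/72.5/95) of log₂ dose. The log₂ scale matches the
quintile analysis and makes "per doubling" the natural effect unit.

**Penalty / prior.** Quadratic roughness penalty λ/2·βᵀSβ with S the
integrated squared second derivative of the fitted curve over the knot
span, computed exactly by 2-point Gauss–Legendre quadrature per
inter-knot interval (the integrand is piecewise quadratic). Linear curves
are exactly unpenalised (S's first row/column vanish). λ is selected by
maximising the Laplace-approximate marginal likelihood over a fixed
log-spaced grid (10⁻² to 10⁶, 17 points) — deterministic and cheap; a
fixed-λ override is available everywhere.

**Mode and sampling.** The penalised mode is found by damped Newton
iteration (step halving, gradient tolerance 10⁻⁹, with a small-ridge
refit fallback under monotone likelihood). Posterior draws come from
adaptive random-walk Metropolis: 4 chains started at the mode, proposal
covariance (2.38²/p)·(−H_pen)⁻¹, proposal scale adapted toward ~30%
acceptance during burn-in only (1000 iterations), 5000 kept draws by
default. Diagnostics record the acceptance rate and the maximum
split-chain R-hat over coefficients; warnings fire outside
acceptance ∈ [0.1, 0.6] or R-hat > 1.05. Seeded chains make every run
reproducible.

**Normalisation.** Reported curves are the relative hazard
r(d) = exp(g(d)) / meanᵢ exp(g(dᵢ)) over the cohort's observed doses, so
the cohort average of r is exactly 1 in every draw and the curve is
invariant to intercept shifts (the Cox model has none). "r = 0.5" reads:
half the population-mean instantaneous recovery rate.

**Threshold diagnostic.** The zero region is the maximal interval
starting at the lowest grid dose where P(r(d) < ε) > 0.95, with
ε = 0.05. A non-empty region ⇒ `threshold_consistent`; empty ⇒
`no_threshold`. Both ε and the probability cutoff are exposed
parameters; the construction is this package's formalisation of the
verbal criterion "hazard is zero until the dose exceeds the threshold".
Because the spline smooths a hard step and ε is strict, the estimated
zero-region edge is a *conservative lower bound* of a true threshold
(typically ~0.2 log₂ units below it at n = 619), which is the safe
direction for the clinical question.

**Known limitation — empirical-Bayes bands.** The credible band
conditions on the selected λ. In small cohorts (n ≈ 200) the marginal
likelihood occasionally selects an effectively linear fit, and the
resulting band understates curvature uncertainty near breakpoints;
measured pointwise coverage of the 95% band on such replicates is ≈ 0.80
under λ selection versus ≈ 0.95 at a fixed moderate λ. The calibration
test therefore fixes λ; accounting for λ uncertainty (e.g. a hyperprior)
is a possible extension.

**Linear fit.** `linear_cox_hr` is the spline model's linear limit
(single slope, no penalty), reported as a hazard ratio per reporting
unit of dose (or per doubling with `scale="log2"`), with Wald 95% CI.

## Concordance

Harrell's C uses the orientation "higher dose ⇒ earlier recovery": a pair
is permissible when the member with the shorter time had an observed
recovery (at equal times, when exactly one recovered); tied event times
contribute no pair, tied scores half credit. The implementation is a
chunked vectorised pair count; tests verify exact agreement with a
pure-loop enumeration oracle and with lifelines. The day-21 endpoint
labels recovery on or before day 21 as 1, excludes deaths before
recovery, and labels recipients censored alive without recovery as 0
(only deaths are excluded in the published analysis; this choice is
configurable in spirit — the labelling function is separate and small).
Its concordance is the AUROC of fitted probabilities from a univariate
logistic model, which coincides with the rank AUROC of the dose for this
monotone model; under complete separation the fit warns and falls back
to the rank AUROC.

## Quintile doubling time

Recovered recipients are split into dose quintiles by rank (stable ties,
sizes within 1). Each quintile contributes its median log₂ dose (the
median of the log₂ values — with even-sized quintiles this differs from
the log₂ of the median dose, and only the former makes the noise-free
linear construction exact) and median recovery interval. Pearson r over
the 5 points measures linearity; the unweighted OLS slope of interval on
log₂ dose, negated, is the doubling time: halving the infused dose
delays reaching any fixed granulocyte level by one population doubling
under exponential expansion. A non-negative slope is flagged as having
no doubling interpretation.

## Pipeline

One YAML config and one master seed drive everything; per-stage seeds are
spawned deterministically, so two runs with the same config are
numerically identical. Sensitivity subsets re-run all stages after
dropping pretransplant-radiation and/or posttransplant-methotrexate
recipients. Logs go to stderr; results never do. Report JSON carries a
schema version and full provenance (config hash, seeds, package version).

## Problem sizes used in tests

Module and acceptance tests run at the study scale (n = 619) for the
scenario-discrimination and calibration checks, n = 10,000 for null
concordance and dose-independence checks, n = 200 × 50 replicates for
band-coverage, and n ≤ 50 for brute-force oracle comparisons; MCMC in
tests keeps 500–1000 draws (the default 5000 is for analysis use).
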