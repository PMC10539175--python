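# graftdose

Dose–response analysis of graft CD34⁺ cell dose versus posttransplant
granulocyte recovery, for transplant biostatisticians and physicians who
want to move beyond discretised "low vs adequate dose" comparisons.

Consensus guidelines assume a *threshold dose* of CD34⁺ cells below which
engraftment fails, and quantify dose per kg of recipient body weight. Both
assumptions are testable. If a threshold exists, the hazard of granulocyte
recovery must be exactly zero below it; if not, the hazard should rise
continuously with dose from zero dose upward. And because blood volume
tracks lean body mass far better than total body weight, dose per litre of
recipient blood volume is a biologically better normalisation than dose
per kg.

`graftdose` implements the full analysis chain:

- **Cohort simulator** — synthetic single-unit cord blood transplant
  cohorts (N = 619 by default, about half adults) with a log-normal
  per-kg dose distribution calibrated to published percentile anchors
  (min/5th/10th/25th ≈ 0.17/0.60/0.83/1.28 × 10⁵/kg), recovery times from
  h(t|d) = h₀(t)·r(d) with a Weibull baseline and an explicit scenario
  curve r (threshold, plateau, log-linear, or flat), a competing hazard of
  death before recovery (~10 per 619), and administrative censoring.
- **Dose metrics** — absolute CD34⁺ count, dose per kg (10⁵ cells/kg) and
  dose per litre of blood volume (10⁷ cells/L), blood volume from lean
  body mass (80 mL/kg LBM default, Nadler formula optional), the
  extreme/normal LBM-to-weight stratification, and the Poisson noise in a
  graft's true HSC content.
- **Penalised-spline Cox model** — the log recovery hazard as a restricted
  cubic spline in log₂(dose) inside a Cox partial likelihood (Efron ties),
  a roughness penalty on integrated squared curvature (weight chosen by
  Laplace-approximate marginal likelihood), and adaptive random-walk
  Metropolis sampling for credible bands. Curves are normalised so the
  cohort-average relative hazard is exactly 1 in every draw. A
  `threshold_diagnostic` reports whether the posterior supports a
  low-dose region of essentially zero hazard.
- **Concordance machinery** — Harrell's C of each dose metric against the
  censored recovery interval, and logistic-model AUROC for recovery by
  day 21 (deaths before recovery excluded), overall and by LBM/BW stratum.
- **Quintile doubling time** — per-quintile median log₂ dose vs median
  recovery interval; under exponential granulocyte expansion the negated
  regression slope is the in-vivo granulocyte doubling time in days.

## Worked example

The dose calculator (also available as `graftdose dose-calc`): a 70 kg
recipient with 50 kg lean body mass receiving a graft of 40 × 10⁵ CD34⁺
cells:

```sh
$ graftdose dose-calc --sex M --weight 70 --cd34 4e6 --lbm 50
{
  "blood_volume_l": 4.0,
  "dose_per_kg_1e5": 0.5714,
  "dose_per_bv_1e7": 0.1
}
```

Blood volume is 80 mL × 50 kg LBM = 4.0 L, so the graft provides
0.57 × 10⁵ cells/kg and 0.1 × 10⁷ cells/L — well below the guideline
"threshold" of 1.5 × 10⁵/kg for cord blood.

The hazard-curve analysis on a simulated cohort whose generative curve
plateaus (no threshold):

```python
import graftdose as gd

cohort = gd.add_dose_columns(gd.simulate_cohort(gd.SimulationConfig(n=619, seed=1)))
post = gd.mcmc_curve_posterior(cohort, "per_bv", n_draws=1000, burn_in=500, seed=2)
v = gd.threshold_diagnostic(post)
q = gd.quintile_summary(cohort, "per_bv")
print("verdict:", v.verdict)
print("low-dose median r:", round(post.median[0], 2), " high-dose:", round(post.median[-1], 2))
print("quintile r:", round(q.pearson_r, 2), " doubling time:", round(q.doubling_time_days, 2), "days")
```

prints

```
verdict: no_threshold
low-dose median r: 0.42  high-dose: 1.05
quintile r: -0.84  doubling time: 1.24 days
```

The fitted relative hazard stays well above zero (≈ 0.4 of the population
mean) even at the lowest observed doses, so the diagnostic returns
`no_threshold`; quintile median interval falls linearly with log₂ dose
(r ≈ −0.84), and each halving of the dose delays recovery by ≈ 1.2 days —
the estimated granulocyte doubling time under this simulation scenario.

The full pipeline (simulate → dose metrics → concordance table → hazard
curves and verdicts per metric → quintile summaries → sensitivity subsets
without pretransplant-radiation / posttransplant-methotrexate recipients)
runs from one YAML config:

```sh
graftdose analyze --seed 1 --out-dir out/
```

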