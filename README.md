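# edss-midpath

Censoring-bias-adjusted estimation of disability progression speed in
relapsing-onset multiple sclerosis from irregular EDSS clinic-visit
records.

## The problem

Disability in MS is scored at clinic visits on the Expanded Disability
Status Scale (EDSS: 0, then half-point steps 1.0–10.0).  Visits are
irregular and often years apart, so the time at which a patient
*irreversibly* reaches an endpoint level (reaches it and never again falls
below it) is interval-censored: it lies somewhere between the last visit
below the level and the visit that attains it.  Taking observations at
face value implicitly assumes **maximum survival time** — disability stays
as last measured until the day of the next visit — which systematically
underestimates progression speed, by an amount that grows with the gaps
between visits.  This package implements the classical midpoint
censoring-bias-reduction strategy for this setting and quantifies its
effect, for epidemiologists and biostatisticians working with
natural-history clinic databases.

## The method

For each patient the package:

1. detects every irreversible endpoint level *e* ≥ 1.0 and its attainment
   time *t_b* (the earliest visit from which the record never again drops
   below *e*), labelling each observation Oo/Of/Om/Or/Ot (onset anchor,
   first / intermediate / last observation at an endpoint, transitory
   high);
2. brackets the unobserved crossing with the **minimum** survival time
   *t_a* (the last record strictly below *e*) and the **maximum** *t_b*;
3. places an expected **midpoint** measure for each level.  When *k*
   consecutive levels are first attained at the same visit (skipped
   levels), the shared bracket (*t_a*, *t_b*] is split into *k* equal
   subintervals and level *j* sits at

   t_j = t_a + (2j − 1)(t_b − t_a) / (2k),

   which reduces to the usual midpoint (t_a + t_b)/2 for k = 1.

Progression speed is then estimated two ways, under each assumption:

* **rate of change** β_yso — a fixed-effects regression of EDSS on years
  since onset through the origin (EDSS 0 at onset is assumed), restricted
  to the near-linear range EDSS ≤ 6, with patient-level cluster-bootstrap
  uncertainty.  Maximum-assumption models are populated with clinical
  observations only; midpoint models add the expected midpoint measures;
* **survival time** — Kaplan-Meier curves p = 1 − f at irreversible
  endpoints EDSS 1–9, with right-censoring at the last clinical
  observation under every assumption.

A synthetic natural-history cohort generator (linear latent progression,
gamma-renewal visit process, onset-to-first-visit delay, Poisson transitory
relapse elevations, gamma follow-up horizons) makes every stage testable by
parameter recovery without any clinical data.

## Worked example

```python
from edss_midpath import (SimulationParams, simulate_cohort, assumption_records,
                          fit_rate, compare_assumptions, endpoint_events, km_fit)

params = SimulationParams(n_patients=500, beta_true=0.17, seed=1)
cohort = simulate_cohort(params)

rec_max = assumption_records(cohort, "maximum")    # clinical observations only
rec_mid = assumption_records(cohort, "midpoint")   # clinical + Exp measures
est_max = fit_rate(rec_max, assumption="maximum", seed=1)
est_mid = fit_rate(rec_mid, assumption="midpoint", seed=1)
comp = compare_assumptions(est_mid, est_max, rec_mid, rec_max, seed=1)

print(f"beta_yso (maximum):  {est_max.beta_yso:.4f} EDSS/year")
print(f"beta_yso (midpoint): {est_mid.beta_yso:.4f} EDSS/year")
print(f"midpoint vs maximum: {comp.pct_faster:.1f}% faster "
      f"(95% CI of difference {comp.diff_ci95[0]:.4f}..{comp.diff_ci95[1]:.4f})")

for a in ("maximum", "midpoint"):
    curve = km_fit(endpoint_events(cohort, 3.0, a))
    print(f"median survival to EDSS 3 ({a}): {curve.median:.1f} years")
```

prints

```
beta_yso (maximum):  0.1572 EDSS/year
beta_yso (midpoint): 0.1633 EDSS/year
midpoint vs maximum: 3.9% faster (95% CI of difference 0.0057..0.0065)
median survival to EDSS 3 (maximum): 18.4 years
median survival to EDSS 3 (midpoint): 17.4 years
```

The true simulated rate is 0.17 EDSS/year and the true EDSS 3 crossing is
at 17.6 years: the maximum-assumption estimates are biased slow, the
midpoint-adjusted estimates sit closer to the truth, and the paired
bootstrap confirms the speed-up is systematic, not noise.

The same analysis runs from the shell:

```bash
edss-midpath simulate --out cohort.csv --seed 1 --n-patients 500
edss-midpath augment --in cohort.csv --out augmented.csv
edss-midpath fit-rate --in cohort.csv --assumption mid --out rate.json
edss-midpath fit-km --in cohort.csv --assumption mid --out km.csv
edss-midpath censoring-report --in augmented.csv --out report.csv
```

or end-to-end with `edss-midpath run --config run.yml`, which emits every
intermediate artifact as plain delimited text plus a JSON manifest of
seeds and record counts.

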