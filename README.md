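# cyclomort

Sibling-matched case-control analysis of tropical-cyclone exposure and
under-five mortality, with gridded attributable-burden estimation.

Tropical cyclones are among the deadliest recurring natural hazards, and
children under five in low- and middle-income countries are especially
exposed: storms injure directly, disrupt care, and degrade water and
sanitation in the weeks that follow. Quantifying that risk from household
survey birth histories is hard because families differ in ways no covariate
list captures. The sibling-matched design solves this by comparing each
deceased child only with its own mother's other children, evaluated at the
same age: every family-level confounder — wealth, location, water source,
maternal characteristics — cancels within the matched set, and what remains
is the contrast in cyclone exposure just before each child reached that
age.

`cyclomort` is a complete, tested pipeline for this analysis, aimed at
environmental epidemiologists who want to study the design itself, run
parameter-recovery experiments, or apply the machinery to their own
(survey, best-track, weather, population-grid) tables:

* **synthetic data** — seeded generators for birth-history cohorts with a
  configurable multiplicative exposure effect on monthly death odds,
  best-track-style storm tables, monthly cluster weather, and
  population/mortality grids;
* **exposure** — R34 wind-radius buffers around densified track fixes,
  haversine point-in-buffer tests, and dichotomous exposure over the lag
  windows 0–30, 31–60, 61–90 and 0–90 days before each reference date;
* **matching** — the study's five exclusion rules and matched-set
  construction with per-control reference dates;
* **model** — a conditional logistic maximum-likelihood fitter (Newton on
  the exact gradient and observed information) with natural cubic spline
  adjustment (df = 6) for window temperature and precipitation, time-trend
  and maternal-age covariates, subgroup Z-tests, stratified analyses and a
  sensitivity suite;
* **burden** — attributable fractions AF = (RR − 1)/RR and gridded excess
  deaths ED = AF · P · M · C with CI-bound ranges.

The core model: for matched set *s* with members *i* and case c(s),

    l(β) = Σ_s [ η_c(s) − log Σ_{i∈s} exp(η_i) ],   η_i = x_i'β,
    OR = e^β,   95% CI = e^(β ± 1.96·se).

The fitter is verified against the closed-form discordant-pair estimator,
brute-force likelihood evaluation, `statsmodels`' `ConditionalLogit`, and a
frozen `survival::clogit` fit from R; the spline basis is verified against
R's `splines::ns`. See `docs/methods.md` for the full model description,
numerical choices, and what the synthetic generators do and do not emulate.

## Worked example

`examples/config.yaml` simulates a 6,000-mother cohort in a cyclone-prone
10°×10° coastal box with a true first-month effect of OR 1.5 injected into
the death odds, then runs the whole pipeline:

```sh
cyclomort run --config examples/config.yaml --out demo/
```

This writes the five input tables plus `matched_sets.csv`, `analysis.csv`,
`fit.json`, `stratified.json`, `sensitivity.json`, `burden.csv` and a
manifest into `demo/`. With the config as shipped (seed 7):

```
lag0:  OR 1.523 (95% CI 1.065, 2.178)  p=0.021  informative_sets=1490
lag1:  OR 1.418 (95% CI 0.967, 2.080)  p=0.074
lag2:  OR 1.043 (95% CI 0.694, 1.569)  p=0.839
lag02: OR 1.331 (95% CI 1.059, 1.673)  p=0.014
cases 1490   controls 3827   controls per case 2.6   deaths <12 months 79.1%
```

Reading the output: the fitted first-month odds ratio 1.523 recovers the
injected 1.5 within its confidence interval; the effect fades in the
second and third months before death (by construction only lag-0 exposure
acts, and lag windows of siblings overlap); 79% of synthetic deaths occur
in infancy, matching the configured death-age distribution. The burden
stage converts the lag-0 OR into an attributable fraction of 34.4% — large
here because the injected demo effect is large — and about 2,850 excess
deaths (95% CI 508, 4,493) over the 2012–2014 demo grid.

Each stage also runs standalone (`cyclomort simulate | match | expose |
fit | burden`), consuming the previous stage's CSV/JSON artifacts, and the
same functionality is importable (`cyclomort.clogit_fit`,
`cyclomort.simulate_matched_sets`, ...).

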