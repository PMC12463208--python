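# Methods

## The design

`cyclomort` implements a sibling-matched case-control analysis of tropical
cyclone exposure and under-five mortality. Every under-five death defines a
matched set: the deceased child is the case, and each sibling of the same
mother that was alive when it reached the case's age at death is a control.
The control's *reference date* is its own birth date shifted forward by the
case's death age in completed months; exposure for every set member is
evaluated relative to its own reference date, so all members are compared
at the same age and all time-invariant family-level confounding cancels in
the conditional likelihood.

Exposure is dichotomous. A location is exposed on a calendar day if it lies
within the R34 radius (the radial extent of 34-kt sustained winds) of any
best-track fix dated that day, with great-circle distance computed by the
haversine formula on a sphere of radius 6,371 km. Tracks are linearly
densified to a 60-minute cadence before matching so a fast storm cannot
step over a small buffer between 6-hourly fixes. Exposure over a lag window
is the disjunction over the window's days; windows are closed day intervals
counted back from the reference date — lag0 = [0, 30], lag1 = [31, 60],
lag2 = [61, 90], lag0–2 = [0, 90], with day 0 the reference date and both
bounds inclusive. Boundary inclusivity is a declared convention tested
explicitly.

## The estimator

For matched set *s* with members *i*, design rows x_i and observed case
c(s), the conditional log-likelihood is

    l(β) = Σ_s [ η_c(s) − log Σ_{i∈s} exp(η_i) ],   η_i = x_i'β.

Only *informative* sets (within-set variation in at least one design
column) contribute; the rest are dropped and counted. The exposure odds
ratio and its confidence interval are OR = e^β and e^(β ± 1.96·se), with
the 1.96 multiplier fixed rather than the exact normal quantile. Subgroups
are compared with Z = (β₁ − β₂)/√(SE₁² + SE₂²) against the standard
normal, two-sided.

Confounder adjustment follows the main specification: natural cubic splines
with six degrees of freedom (interior knots at equal quantiles of the
pooled analysis sample, boundary knots at the extremes, truncated-power
natural basis equal in span to R's `splines::ns`) for the window-aggregate
mean temperature (°C) and cumulative precipitation (mm); a linear calendar
year term plus eleven calendar-month indicators for time trends; and
maternal age at the reference date (years, linear). Each lag window gets
its own model with the weather aggregated over that same window
(one-lag-per-model; monthly series averaged/summed over the calendar
months the window overlaps). The infant-mortality secondary outcome
restricts sets to cases that died before 12 months.

### Numerics

The fitter is a Newton iteration on the exact gradient and observed
information with step-halving, a trust-region cap of 20 on the (scaled)
step norm, initialization at β = 0, gradient tolerance 1e-8 (max-norm) and
at most 100 iterations. Covariates are centered within sets (the
conditional likelihood is invariant to set-level shifts) and scaled to unit
variance; columns with no within-set variation anywhere, or numerically
collinear with earlier columns (greedy orthogonalization, relative residual
below 1e-7), are dropped — the exposure column always comes first and is
never dropped. Standard errors come from the inverse observed information
at the optimum. An exposure coefficient beyond |β| > 15 (OR beyond ~3×10⁶)
is reported as non-converged: that is the separation signature of a binary
exposure. Nuisance spline coefficients may be weakly identified at small
sample sizes (their likelihood is nearly flat); the fit then still reports
the exposure term with its proper standard error, matching the behaviour
of `survival::clogit`.

## The burden calculation

With the fitted OR read as a relative risk RR (defensible because
under-five death in any month is rare), the attributable fraction among
the exposed is AF = (RR − 1)/RR and the excess deaths in grid cell g and
year y are

    ED[g,y] = AF · P[g,y] · M[g,y] · C[g,y]

where P is the under-five population, M the under-five mortality rate
(each cell carries its country's national rate) and C the number of
distinct storms whose R34 buffer covered the cell centroid during that
year. Counting distinct storms per cell-year (not fixes, not months) keeps
ED independent of track sampling cadence; deciding coverage at the cell
centroid matches the 10-km aggregation of the population grid. Uncertainty
totals substitute the CI bounds of the OR for RR.

## The synthetic-data generator

No survey microdata, best tracks, reanalysis weather or population grids
are downloaded; the generator emulates their statistical structure under
one integer seed, bit-reproducibly.

* **Cohort.** Mothers are assigned to clusters scattered uniformly in the
  bounding box (about one cluster per 25 mothers; 22% urban; three
  synthetic countries split by longitude terciles). 10% of households are
  single-child (so the exclusion rule is exercised); the rest have 2–5
  children with 18–42 months of birth spacing. Household covariates use
  the field's standard category sets (water: piped/bottled, well, natural,
  other; toilet: flush, pit, none, other; housing finished/unfinished;
  maternal education in three levels) with marginals close to what
  multi-country surveys report for cyclone-prone LMICs.
* **Deaths.** A discrete per-month hazard is calibrated so the cumulative
  probability of death by 60 months equals `baseline_death_prob` (default
  0.08) and the marginal death-age distribution over the five yearly bins
  matches `death_age_distribution` (default 79.5/10.8/4.7/2.6/2.4% — deaths
  concentrated in infancy). When the child's cluster has an exposed day in
  the 30 days up to its month-m reference date, the odds of death in month
  m are multiplied by `true_or` — exactly the lag-0 estimand of the
  analysis, so generator and model are aligned by construction.
* **Tracks.** Storms are piecewise-linear paths with small random heading
  perturbations, moving at `storm_speed_kmh` (default 20 km/h, i.e., about
  120 km between 6-hourly fixes), gale-force winds (35–120 kt) and an R34
  radius random-walking within `r34_range_km`. No meteorological realism
  is claimed beyond what the buffer geometry needs.
* **Weather.** Monthly temperature is a seasonal sinusoid with a latitude
  gradient plus Gaussian noise; monthly precipitation is gamma-distributed
  with a seasonal scale, hence non-negative by construction.
* **Grid.** Cell centroids at a configurable spacing (10 km by default)
  with log-normal under-five populations and country-year mortality rates
  drawn in [0.02, 0.10].

A second generator, `simulate_matched_sets`, samples matched sets directly
from the conditional model: members get i.i.d. Bernoulli exposure and the
case is drawn with probability proportional to `true_or^exposed` (via the
Gumbel-max trick), keeping only exposure-discordant sets. Because this is
exactly the likelihood the fitter maximizes, it is the reference generator
for parameter-recovery and CI-calibration studies: with 5,000 informative
sets per replicate the estimator recovers a true OR of 1.5 with mean error
below 0.01 and 95% CI coverage of about 0.956 (measured over 1,500
replicates during development).

### What passing tests do and do not show

The cohort generator reproduces the *structure* the analysis assumes, not
real data: no survey sampling weights, no recall error in birth/death
dates, no spatial clustering of risk, no secondary hazards (flooding), and
exposure prevalence far below real cyclone seasons unless storms/radii are
enlarged. At desk scale the number of exposure-discordant sets per cohort
is small (tens to hundreds), so cohort-level estimates are noisy and the
end-to-end tests assert direction and CI behaviour rather than tight
recovery; sibling designs also carry a small survivor-selection
attenuation when the same exposure process acts across the whole of each
control's childhood. Calibration claims are therefore established on the
direct matched-set simulator, where the generating process and the
estimand coincide exactly.

## Problem sizes and runtime

Defaults are chosen so the full test suite runs in about a minute and a
demo pipeline in a few seconds on one CPU: cohorts of 600–6,000 mothers,
6–12 storms, 10-year windows, burden grids at 50–200 km spacing over a
10°×10° box, and calibration studies of 1,000 replicates × 5,000 sets.
All are configuration parameters, not limits; the estimator itself is
vectorized over set members and fits ~20,000-row designs with 26 columns
in a handful of Newton iterations.

## Known limitations

* Circular, quadrant-symmetric R34 buffers; no wind-field model, no
  pressure-based intensity, no flood proxy.
* Exposure requires gale intensity (≥34 kt) at the matching fix, not
  anywhere along track — a declared reading where the convention is
  ambiguous.
* Death ages are in completed months; reference-date arithmetic shifts by
  calendar months preserving the day-of-month with end-of-month clamping.
  Day-resolution death dates are not modelled.
* A deceased sibling that outlived the case's death age is
  control-eligible (it was alive and observable at the matched age); a
  control must have reached that age by the survey date.
* The grid burden inherits the national-rate approximation for cell
  mortality and a uniform effect estimate across cells.
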