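# Methods

## The trajectory model

Mean medical cost per month per capita around disease onset is modelled as

    C(m) = c + (δ + (P − δ) e^(−r m)) · I(m ≥ 0),     m = −20 … 20,

with month offsets counted in calendar months from the onset month (m = 0).

| parameter | meaning | units | notes |
|---|---|---|---|
| `c` | pre-diagnosis plateau ("initial comorbidity") | USD/month | cost level of the cohort before diagnosis; measures comorbidity burden in dollars |
| `P` | cost of onset | USD | excess over `c` in the onset month |
| `r` | population recovery rate | 1/month | exponential slope of the post-onset decline; unconstrained in sign, but the recovery interpretation applies to positive values |
| `δ` | acquired comorbidity | USD/month | post-onset asymptote minus pre-onset plateau |

Assumptions: a flat pre-onset plateau (pre-diagnosis cost ramps observed for
some conditions, e.g. asthma or dementia, are deliberately not modelled);
a single onset per person within the window; no interaction with other
health events inside the ±20-month window beyond death, which enters only
through censoring.

### Fitting

`TrajectoryModel.fit()` minimises Σᵢ wᵢ (Cᵢ − C(mᵢ))² over the usable
profile points.

* **Weighting.** Default `inverse_variance` (wᵢ = 1/σᵢ²), matching the
  χ²/σᵢ² goodness-of-fit diagnostic; parameter covariance is the unscaled
  (absolute-sigma) Gauss-Newton covariance, since the σᵢ are real standard
  errors. An `unweighted` mode is provided; there the covariance is scaled
  by the residual variance. Months with σᵢ = 0 (fewer than two at-risk
  persons, or degenerate noiseless data) are flagged and excluded from
  weighted fits.
* **Optimisation.** Levenberg-Marquardt with an analytic Jacobian,
  multi-start over r ∈ {0.05, 0.2, 0.5, 1, 2}/month; c starts at the
  weighted pre-onset mean, P at (month-0 value − c), δ at (post-onset tail
  mean − c). Each start is polished by restarting from its own optimum;
  best weighted SSR wins. Tolerances 1e−14 (xtol/ftol), 20,000 function
  evaluations per start. On noiseless model-generated profiles the fit
  recovers generating quadruples with r ∈ [0.05, 3] to better than 1e−6
  relative (property-tested).
* **Degenerate model.** When the full fit fails, or se_r/|r| exceeds a
  relative-SE threshold (default 10, configurable), or r̂ ≤ 0 with δ̂ itself
  unidentified, the step model C(m) = c + P·I(m ≥ 0) is used; its weighted
  closed form is the pre-onset and post-onset weighted means. The threshold
  default is a documented choice — the identifiability rule is not uniquely
  determined by the fit alone. The step fit needs only one point on each
  side of onset; the full fit requires ≥5 usable points including ≥1
  pre-onset and ≥2 post-onset.
* **Goodness of fit.** χ²/df = Σᵢ (Cᵢ − C(mᵢ))²/σᵢ² / df with
  df = (points used) − (parameters), 41 − 4 = 37 for a complete profile.
  The sum runs over the monthly points by default; the two-month grouping
  used when plotting is available via `group_months=2` but is presentational
  — calibration of the statistic (mean ≈ 1 under a correct model) holds for
  the monthly sum with df = 37, not for the grouped sum.
* **Intervals.** `conf_int()` uses normal quantiles on the delta-method
  standard errors. Per-parameter coverage is verified at its nominal 95%
  by simulation (0.947–0.960 over 1,000 replicates). The joint event that
  all four correlated intervals cover simultaneously has probability
  ≈ 0.84, which matters when counting "fully recovered" diseases in the
  end-to-end suite (expected 10.1 of 12, binomial SD 1.26).

## Onset ascertainment conventions

* 0.3 years = 0.3 × 365.25 = 109.575 days; integer day gaps ≤ 109 qualify.
* The confirming record must be strictly later than the earliest
  qualifying record; same-date records never confirm. If the earliest
  qualifying record is not confirmed, there is no onset — later confirmable
  pairs do not substitute.
* Prevalence exclusion scans **any** diagnosis position and **any** claim
  source (a config switch restricts it to primary positions, since the
  convention is not uniquely fixed); onset detection requires the primary
  position in one of the four qualifying sources.
* Incident cohorts keep onsets in (interview, interview + 5 years], with
  the sex restrictions applied (breast cancer: women; prostate cancer: men).
* Dates are calendar dates without time of day.

## Cohort and profile conventions

* Claims are CPI-adjusted to year-2000 dollars with the medical-care CPI
  (annual averages; packaged series 1990–2005, base 2000); adjustment is
  amount × index(2000)/index(year).
* Month binning is by calendar month: a claim in the onset month has
  m = 0 regardless of day. This avoids day-count drift across 41 bins.
* The death month itself remains at risk (partial-month costs are real
  outlays); months strictly after it are censored, as are months outside
  enrollment. Zero-cost at-risk months are real observations and enter the
  means (per-capita semantics).
* Profile SE is the unbiased sample SD over at-risk persons divided by √n;
  optional per-person survey weights give a weighted mean with an
  effective-sample-size SE but default to 1 (national weighting is out of
  scope).
* The Charlson index (Quan ICD-9 coding, 17 groups, original weights,
  hierarchy rules) is computed over the year before the interview by
  default; the same function accepts any index date, so a rolling
  12-month per-month index is available.
* Age at diagnosis uses the 80.0-year boundary inclusive on the younger
  side; 2.5-year survival uses death within 913 days of onset.

## The synthetic generator

The generator produces person/claims tables with known truth. What it
emulates: trajectory-model cost dynamics around true onsets (using the
published total-population quadruples as the default generating truth for
the twelve diseases); competing per-month onset hazards; post-onset
mortality as a per-month Bernoulli hazard (populating the 2.5-year
survivor/non-survivor strata naturally); qualifying two-record onset
signals with configurable confirmation delays; prevalent-case and
single-record (unconfirmed) contamination; planted chronic-condition
marker codes in the pre-interview year for the Charlson index; three-level
disability; and nominal-dollar claims through the CPI series so the
adjustment step is exercised nontrivially.

Default study conditions and why:

* `onset_hazard` = 0.002/month per disease. Real per-disease incidence
  spans two orders of magnitude and would leave the rarest diseases with a
  handful of cases at testbed population sizes; a common hazard yields
  ~60–130 incident cases per disease per 1,000–2,000 persons, enough to
  identify all four parameters for every disease. The hazard is per-disease
  configurable.
* `noise_sd` = 250 USD/month, Gaussian on monthly totals, truncated at 0.
  The truncation mass is negligible (< 0.1%) at the smallest preset
  plateau, so monthly means stay on the model curve and profile SEs are
  ≈ noise_sd/√n. A dispersion matching real claims (≈ $2,000/month implied
  by published SEs at published cohort sizes) would make a truncated
  Gaussian itself badly biased; the Gaussian form is the simplest structure
  consistent with a means/SEs analysis and is a config knob, not a claim
  about real claims distributions.
* `prevalent_fraction` = 0.07 and `single_record_fraction` = 0.05,
  matching the order of prevalence exclusions in published cohort tables;
  `confirm_delay_days` uniform on [7, 90] (within the 109-day window);
  `death_hazard_post_onset` = 0.01/month (≈ 26% dead by 2.5 years).
* Diagnosis-marker claims (onset confirmations, planted comorbidity codes)
  carry zero paid amount so that each person's monthly claim totals equal
  the model series exactly when noise is off (conservation is tested).
  Planted comorbidity codes avoid the twelve diseases' pattern sets by
  default so they never create accidental prevalent cases.
* Inpatient stays are not split across months; each claim's cost belongs
  to the service month of its start date.

What it does **not** emulate — and what passing tests therefore do not
show about real data: skewed/zero-inflated cost distributions; seasonality
and end-of-life cost escalation; code-position noise, miscoding and claim
lag; per-disease incidence gradients; disability dynamics over time;
correlation between comorbidity and onset risk (planted conditions are
independent of case status); and multiple onsets per person. Conclusions
about estimator behaviour transfer only to the extent the means/SEs
summary is the relevant statistic.

## Population forecast conventions

* Time `x` and the hazard are in months, consistent with r's units.
* Mortality is excluded inside the forecast by assumption (the cohort is
  subject to no other health event); death-inclusive forecasting is a
  non-goal.
* Constant-hazard input: closed form, with the confluent r = h branch
  (h·x·e^(−hx)) engaged below |r − h| = 1e−12 and verified continuous
  against the generic branch. The adaptive-quadrature path (absolute
  tolerance 1e−10·(c+P)) exists as an independent cross-check and agrees
  with the closed form to better than 1e−8 relative.
* Tabulated (Kaplan-Meier) input: right-continuous step survival with
  point-mass density at event times, making the integral an exact finite
  sum. The product-limit computation is cross-checked against lifelines.

## Problem sizes

The test suite exercises populations of 250–2,000 persons (the end-to-end
recovery check uses 2,000 persons and all twelve diseases), 200-replicate
calibration of χ²/df and interval coverage, and 10,000 random claim sets
for the onset-rule oracle. The acceptance script's fixed-point computation
uses the 41-point noiseless profile. These sizes identify every parameter
and keep the full suite in the low minutes on one CPU.

## Known limitations

* The trajectory model ignores pre-onset cost ramps; for conditions with
  long diagnostic lead-up the fitted `c` averages over part of the ramp.
* Normal-approximation intervals for `r` degrade when the post-onset decay
  is slow relative to the 20-month window (r ≲ 0.05/month) or when P ≈ δ;
  the step fallback handles the limit but intermediate cases can have
  poorly calibrated `se_r`.
* The forecast treats the onset-time distribution as known; uncertainty in
  S(x) is not propagated.
* The generator's single-onset, independent-comorbidity design cannot
  probe confounding between comorbidity and incidence.
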