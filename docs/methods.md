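# Methods

This note documents the statistical model behind `dyadcea`, the numerical
choices made in the implementation, the scope of the synthetic generator,
and known limitations. Notation: arm *i* = intervention, *c* = control;
λ = willingness-to-pay threshold; the trial window is 540 days with
assessments at baseline and ~180/360/540 days.

## 1. Valuation

EQ-5D-3L responses are levels 1–3 on five dimensions (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression), giving
243 states. A tariff maps states to utilities in one of two forms:

* **additive decrement** — u(s) = intercept − Σ_d dec(d, level_d), with
  decrements for levels 2 and 3 of each dimension (the common published
  regression form);
* **lookup table** — an explicit utility for each of the 243 states.

Validation at load time: all coefficients present (missing ones are named
in the error, e.g. `anxiety_depression:3`), finite utilities, and full
health `11111` attaining the maximum. The shipped country value sets are
**synthetic stand-ins** (see the README tariff note); `toy_linear`
(u = 1 − 0.1·Σ(level−1)) is exact and is what the unit tests use.

Secondary outcomes: the QoL-AD composite (2·self + proxy)/3 on the 13–52
scale, missing if either rating is missing; MMSE (0–30); ZBI-12 burden
inverted as 48 − raw so higher is better on every reported scale.
Secondary-outcome effects are baseline→18-month change scores.

## 2. QALYs

Per participant, utilities at the four visits are joined linearly and
integrated (trapezoid rule) over the **actual** inter-visit days, divided
by 365.25. The rule is exact for the piecewise-linear path, which is why
the test suite checks it against a fine-grid midpoint integration oracle
at 1e-10.

* **Complete-case rule**: a participant missing any follow-up utility has
  no total QALY.
* **Death rule**: utility is 0 from the day of death to day 540 and the
  trajectory counts as complete (the path to death uses the last
  observed utility).
* **Discounting**: outcomes and costs beyond the first year are
  discounted at 3% per year. Default reading (`single_factor`): the
  third 6-month interval (and cost episodes on day ≥ 360) are multiplied
  by 1/(1 + r), since that whole interval lies in trial year two. A
  `mid_interval` alternative discounts continuously from month 12 by
  (1+r)^−(t_mid/365.25 − 1). With r = 0 both are the identity.

Dyad QALYs sum the two members' totals and are defined only when both are
complete.

## 3. Costs

Cost episodes carry setting (inpatient/outpatient), clinic type,
personnel type, cost, and length of stay. Missing costs are imputed from
reference means computed on the observed episodes **pooled across arms**
(imputation must not be arm-informative), with fallback hierarchy:

1. mean by (setting, clinic, personnel);
2. mean by (setting, clinic) — also used when personnel is missing;
3. inpatient mean cost **per day** × length of stay.

An episode resolvable at no level raises an error naming the episode.
Every imputed value records its provenance. Totals aggregate over the
half-open window [0, 540) days (day-540 episodes excluded and counted),
with day ≥ 360 episodes discounted by the same factor as the third QALY
interval. Participants without episodes get zero-cost rows — a zero
total is data, not missingness. Cost totals enter analyses only for
participants with register coverage over the whole window (their dyad
attended the final visit, or the participant died during the trial).

Intervention delivery costs default to 173 per intervention-arm person
with MCI (tablet 100 + 18 months of mobile data 43 + nurse training time
30) and are a sensitivity-analysis option, not part of the base case.

## 4. Incremental analysis

ΔC and ΔE are mean differences (intervention − control) over the units
with non-missing values; cost and effect sample sizes may legitimately
differ. The ICER ΔC/ΔE is reported as:

* **Dominated** if ΔC > 0 and ΔE < 0; **Dominant** if ΔC < 0 and ΔE > 0;
* **Undefined** if ΔE = 0;
* otherwise a ratio; south-west ratios (ΔE < 0, ΔC ≤ 0) are reported as
  the positive magnitude with an `(SW)` annotation, because the bare
  number inverts its decision meaning in that quadrant.

NMB = ΔE·λ − ΔC. Displayed ICERs/NMBs round to the nearest currency
unit; full precision is carried internally, and both the
rounded-inputs path (reproducing printed worked examples from rounded
ΔC/ΔE) and the full-precision pipeline path are exposed.

**Uncertainty** comes from a nonparametric bootstrap stratified by arm:
units (participants; dyads in dyad analyses) are resampled with
replacement within arm, preserving arm sizes, B = 5000 by default. A
resample's ΔE* averages the non-missing effects among the drawn units, so
differing cost/effect sample sizes are preserved along with the
cost–effect correlation. The same resamples give percentile 95% CIs, the
CE-plane quadrant counts (boundary zeros assigned deterministically to
the positive side), and CEAC(λ) = fraction of resamples with
ΔE*·λ − ΔC* > 0 (strict) on a λ grid of 0–200,000 in steps of 1,000.
Default thresholds: 48,876 (site A analyses) and 30,000 (site B and
pooled scenarios).

## 5. Missing data

Multiple imputation by chained equations with **type-1 predictive mean
matching**: per column, a Bayesian linear regression draw (σ² from a
scaled inverse-χ², β from its posterior normal via Cholesky) produces
predicted means; each missing row receives the observed value of one of
its k = 5 nearest donors by predicted mean, so imputations stay on the
data's support (the tariff's representable utilities). Ten chained
iterations per imputation, m = 20 imputations by default, all randomness
through one passed `numpy` Generator (bit-reproducible). Predictors: age,
sex, education, living arrangement, arm, baseline MMSE/ZBI/QoL-AD
(dyad-level, broadcast to both members), and the partner's baseline
utility. QALYs are imputed at the utility level (u1–u3), then integrated;
costs stay complete-case in the MI sensitivity analysis.

Pooling follows Rubin's rules: point estimates average per-imputation
estimates; total variance = mean within-imputation variance + (1 + 1/m) ×
between-imputation variance, with within-variances recovered from the
per-imputation bootstrap CI widths. The engine is hand-rolled because the
established MICE implementation available here draws from the global
RandomState and cannot be driven by a passed Generator, which breaks
seeded reproducibility (see the design ledger).

## 6. Sensitivity, subgroups, scenarios

The default grid per population: base case; MI-completed QALYs;
intervention delivery costs added (MCI and dyad analyses); zero-cost
units removed (per analysis population — the unit's own zero total);
sex and age (≤70 / >70) splits; baseline MMSE ≤26 / >26 (MCI); baseline
inverted ZBI >31 / ≤31 (caregivers); app-use splits at 125 first-year
launches. Usage splits filter the intervention arm only and compare each
stratum against the **full** control arm, which has no usage. Report
rows self-validate: a Dominated label requires ΔC > 0 ∧ ΔE < 0, and
ratio rows must match |ΔC/ΔE| within rounding tolerance. Scenario runs
re-execute the pipeline under a substituted tariff and threshold and can
pool two sites (ids prefixed to avoid collisions).

## 7. Synthetic generator

One seeded `numpy` Generator; fixed draw order (covariates → baseline
utilities → visit days → dropout → death → utility noise → MMSE → QoL-AD
→ ZBI → app launches → item missingness → costs), so a seed is
bit-reproducible. Components:

* **Utilities**: baseline latent utility per member with within-dyad
  correlation ρ = 0.3 (shared + individual Gaussian factors); per-arm,
  per-role linear drift per 6-month interval; an additive caregiver
  treatment effect at follow-up visits; visit-level Gaussian noise;
  the latent value is snapped to the **nearest representable tariff
  utility** (ties toward fewer problems) to produce an EQ-5D-3L state.
* **Visit days**: nominal 0/180/360/540 plus Gaussian jitter (SD 9 days),
  shared within dyad, minimum 30-day spacing; out-of-window visits arise
  naturally and the QALY integration uses the actual days.
* **Dropout**: dyad-level, monotone, missing-at-random: per-visit
  probability expit(logit(base_arm) + β·(dyad mean baseline utility −
  center)) with β = −4 (lower utility → more dropout) and per-arm base
  rates 0.088/0.064 (differential attrition ≈ 24% vs 18% cumulatively).
* **Costs**: per participant per 6-month interval, zero with probability
  0.35, otherwise gamma(shape 0.4, scale 8,900) — right-skewed with a
  heavy zero mass; interval totals are split into 1 + Poisson(1)
  episodes by symmetric Dirichlet shares, assigned inpatient with
  probability 0.15 (with lengths of stay), clinic and personnel types
  drawn categorically; 3% of costs (and some personnel fields) are
  masked to exercise imputation; register coverage ends at the last
  attended visit.
* **Secondary outcomes**: MMSE baseline clipped to the 20–28 eligibility
  band; QoL-AD self/proxy and ZBI with per-arm drifts; app launches
  lognormal(4.83, 1.0) in intervention dyads; 2% item-level MCAR
  missingness at follow-ups only. Death is off by default.

**Ceiling/discretization attenuation.** Because latent utilities are
snapped to a discrete grid with a ceiling at full health, an additive
latent shift δ produces a *smaller* observable QALY difference. The
mapping T is a step function constant on cells bounded by midpoints of
adjacent distinct tariff utilities, so for latent X ~ N(μ, σ²),
E[T(X)] = Σ_g u_g · [Φ((e_{g+1}−μ)/σ) − Φ((e_g−μ)/σ)] exactly
(`expected_mapped_utility`). `expected_caregiver_delta_qaly` assembles
the exact observable ΔE from these per-visit expectations at the nominal
schedule (visit-day jitter is mean-zero, so the expectation is
unaffected), and `caregiver_effect_for_delta_qaly` inverts it by Brent's
method so simulations can target an observable effect directly. The
latent-scale closed form ΔE = δ·(Δt₀/2 + f₂Δt₁ + f₃Δt₂)/365.25 (f_k the
discount factors) is available by omitting the tariff.

## 8. Numerical choices

* Year length 365.25 days; window [0, 540) half-open.
* Percentile bootstrap CIs (2.5/97.5); quantile interpolation as numpy's
  default (`linear`).
* CEAC uses a strict inequality; boundary zeros on the CE plane go to the
  positive side deterministically.
* z = 1.959963984540054 for Rubin-pooled normal CIs.
* Ridge 1e-8 on normal equations and 1e-12 jitter on the posterior
  Cholesky in the MI engine, for numerical stability only.
* Nearest-state inversion resolves exact utility ties toward the state
  with fewer problems, then lexicographically smallest digits.
* Displayed ICERs/NMBs round half-to-even to the nearest currency unit.

## 9. Limitations

* The shipped country tariffs are synthetic stand-ins; absolute utility
  levels under them carry no external meaning. Replace with licensed
  coefficient files before real-data use.
* The generator's cost model draws interval totals independently across
  intervals and participants (no cost autocorrelation, no cost–utility
  dependence), and dropout depends only on baseline utility — MNAR
  mechanisms are out of scope.
* Complete-case base case is biased under differential MAR dropout (that
  is the point of the MI sensitivity analysis and of the bias-reduction
  test); MI assumes MAR given the included predictors.
* Rubin within-variance is recovered from percentile-bootstrap CI widths,
  which treats those intervals as symmetric normal approximations.
* No plotting: the CE plane and CEAC are emitted as CSV coordinates.
* The `single_factor` discount reading treats each 6-month interval as a
  block; mid-interval continuous discounting is available but not the
  default.
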