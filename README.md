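# dyadcea

Within-trial cost-effectiveness analysis for dyadic randomized controlled
trials, plus a synthetic dyadic-trial generator with known ground truth.

The package implements the full analysis pipeline of a pragmatic two-arm
trial in which the randomized unit is a *dyad* — a person with mild
cognitive impairment (MCI) and their informal caregiver — assessed at
baseline and roughly 6, 12 and 18 months:

1. **Valuation** — EQ-5D-3L responses (243 health states) are valued
   through a pluggable country tariff (additive-decrement or full
   243-state lookup form); secondary outcomes are the weighted QoL-AD
   composite (self rating counted twice the proxy rating), MMSE, and the
   ZBI-12 inverted so higher always means better.
2. **QALYs** — trapezoid area under the utility curve over the *actual*
   days between visits; complete-case by default; participants who die
   contribute utility 0 from the day of death and count as complete; the
   final 6-month interval is discounted at 3% per year.
3. **Costs** — episode-level health care costs aggregated over the
   18-month window `[0, 540)` days; missing episode costs imputed from
   stratified reference means with a three-level fallback (setting ×
   clinic × personnel → setting × clinic → inpatient cost per day ×
   length of stay); optional intervention delivery costs (tablet, mobile
   data, nurse training) added to intervention-arm recipients.
4. **Incremental analysis** — ΔC and ΔE as mean differences; dominance-
   aware ICERs (dominated / dominant / undefined / south-west-annotated
   ratios); net monetary benefit ΔE·λ − ΔC; a within-arm stratified
   nonparametric bootstrap drives percentile confidence intervals, the
   four-quadrant cost-effectiveness plane and the acceptability curve
   CEAC(λ) = P(ΔE*·λ − ΔC* > 0).
5. **Missing data** — multiple imputation by chained equations with
   type-1 predictive mean matching, pooled by Rubin's rules, fully
   seedable.
6. **Sensitivity, subgroup and scenario analyses** — imputed-QALY and
   intervention-cost variants, zero-cost removal, sex/age/MMSE/ZBI/app-use
   subgroups (usage strata compare against the full control arm), and
   second-site scenarios with a substituted tariff, willingness-to-pay
   threshold, and optional pooling of sites.

Analyses run at three population levels — people with MCI, caregivers,
and dyads (summed member outcomes, both members required).

> **Tariff note.** The named country value sets shipped under
> `dyadcea/tariffs/` (`*_synthetic.csv`) are *synthetic stand-ins* with
> realistic structure and range, not licensed published coefficients.
> They are replaceable data assets: point `load_tariff()` at a licensed
> coefficient CSV for real-data use. Only `toy_linear`
> (utility = 1 − 0.1·Σ(level−1)) is exact by construction, and the test
> suite relies solely on it.

## Worked example

```python
from dyadcea import (AnalysisConfig, SimulationConfig, builtin_tariff,
                     generate_trial, run_base_case, unit_frame, incremental)

tariff = builtin_tariff("swedish_experience_based")
config = AnalysisConfig(wtp_threshold=48876, bootstrap_B=5000, seed=1)
trial = generate_trial(SimulationConfig(n_dyads_per_arm=170, seed=1))

report = run_base_case(trial, "mci", config, tariff=tariff)
print(report.to_markdown())
```

prints (this exact output is reproduced by the code above):

```
| scenario   | population   | effect_name   |   delta_cost |   delta_effect |    icer |   nmb |
|:-----------|:-------------|:--------------|-------------:|---------------:|--------:|------:|
| base_case  | mci          | QALY          |     2008.196 |          0.016 | 122,551 | -1207 |
| base_case  | mci          | QoL-AD        |     2008.196 |          0.504 |   3,983 | 22635 |
| base_case  | mci          | MMSE          |     2008.196 |          0.407 |   4,930 | 17901 |
```

and a caregiver-level analysis with full bootstrap uncertainty:

```python
frame = unit_frame(trial, "caregiver", "qaly", tariff)
res = incremental(frame, config)
print(f"caregiver ΔC = {res.delta_cost:.0f}  "
      f"(95% CI {res.ci_cost[0]:.0f} to {res.ci_cost[1]:.0f})")
print(f"caregiver ΔE = {res.delta_effect:.4f} QALYs "
      f"(95% CI {res.ci_effect[0]:.4f} to {res.ci_effect[1]:.4f})")
print(f"ICER = {res.icer.display()}   NMB at 48,876 = {res.nmb:.0f}")
print(f"P(cost-effective at threshold) = "
      f"{res.cloud.probability_cost_effective(48876):.2f}")
```

```
caregiver ΔC = -919  (95% CI -2708 to 767)
caregiver ΔE = -0.0052 QALYs (95% CI -0.0364 to 0.0265)
ICER = 176,620 (SW)   NMB at 48,876 = 665
P(cost-effective at threshold) = 0.72
```

(The `(SW)` annotation marks a south-west-quadrant ratio — cheaper but
less effective — where the bare number inverts its decision meaning.)

## Command line

```bash
dyadcea simulate --out demo --seed 7 --dyads 60
dyadcea analyze demo --tariff swedish_experience_based \
    --bootstrap-b 2000 --seed 7 --out demo/analysis
dyadcea report demo/analysis
```

```
simulate: seed=7 dyads/arm=60 -> demo
analyze: population=mci seed=7 B=2000 wtp=48876.0 dataset_hash=dd48e8147dab
analyze: wrote demo/analysis/incremental.json, ce_plane.csv, ceac.csv, report.csv
report: -> demo/analysis/report.md
```

`analyze` emits the incremental summary (`incremental.json`), the
bootstrap cost-effectiveness plane (`ce_plane.csv`), the acceptability
curve (`ceac.csv`) and the results table (`report.csv`; add
`--sensitivity` for the full sensitivity/subgroup grid). `qaly` and
`costs` expose the intermediate per-participant tables. File schemas are
documented in `src/dyadcea/schemas/columns.md`.

## Synthetic generator

`generate_trial(SimulationConfig(...))` draws a complete trial — dyad-
correlated latent utilities mapped to the nearest representable EQ-5D-3L
state, jittered visit days, dyad-level monotone missing-at-random dropout
with per-arm base rates, zero-inflated gamma costs split into episodes,
MMSE/QoL-AD/ZBI trajectories and app-launch counts — from a single seeded
generator, so every dataset is bit-reproducible. The ground-truth
configuration travels with the dataset (`truth.json`).

Because latent utilities are snapped to a discrete utility grid with a
ceiling at full health, an additive latent effect is *attenuated* in the
observable QALY difference. `expected_caregiver_delta_qaly` computes the
exact observable effect implied by a configuration, and
`caregiver_effect_for_delta_qaly` inverts it, so simulation studies can
set treatment effects directly on the QALY scale. See
`docs/methods.md` for the model and all numerical choices.

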