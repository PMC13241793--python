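# File schemas

## visits.csv (long, one row per attended visit)

| column         | type    | notes                                              |
|----------------|---------|----------------------------------------------------|
| participant_id | str     | unique per person                                  |
| dyad_id        | str     | links the person with MCI and their caregiver      |
| role           | str     | `person_with_mci` or `caregiver`                   |
| arm            | str     | `intervention` or `control`                        |
| visit_index    | int     | 0 (baseline) .. 3 (~18 months)                     |
| actual_day     | int     | days from baseline; visit 0 is day 0               |
| eq5d_state     | int     | five-digit EQ-5D-3L state (e.g. 21232); may be missing |
| mmse           | float   | 0..30, people with MCI only                        |
| qolad_self     | float   | 13..52, self rating (MCI member's rows)            |
| qolad_proxy    | float   | 13..52, caregiver's proxy rating (MCI member's rows) |
| zbi_raw        | float   | 0..48, caregivers only                             |
| deceased       | bool    | death flag                                         |
| death_day      | float   | day of death when deceased                         |

## costs.csv (one row per cost episode)

| column              | type  | notes                                        |
|---------------------|-------|----------------------------------------------|
| participant_id      | str   |                                              |
| day                 | int   | days from baseline                           |
| setting             | str   | `inpatient` / `outpatient`                   |
| clinic_type         | str   | e.g. primary_care, memory_clinic             |
| personnel_type      | str   | physician/nurse/other; may be missing        |
| cost                | float | ≥ 0; missing costs are imputed downstream    |
| length_of_stay_days | float | ≥ 1 for inpatient episodes                   |

## participants.csv (one row per person)

participant_id, dyad_id, role, arm, age, sex, education,
living_arrangement, app_launches (intervention dyads, first-year count),
dropout_visit (first missed visit index; empty for completers),
death_day.

## Tariff coefficient CSV

Columns `form, term, level, coefficient`; `form` is
`additive_decrement` (term = dimension name or `intercept`, level 2/3)
or `lookup_table_243` (term = five-digit state, level empty).

## qaly.csv (written by the CLI)

participant_id, interval_1, interval_2, interval_3, total, complete.

## participant_costs.csv (written by the CLI)

participant_id, dyad_id, role, arm, inpatient_total, outpatient_total,
intervention_total, grand_total.
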