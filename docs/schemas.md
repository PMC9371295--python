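# File formats

All tabular artifacts are UTF-8 CSV with a header row and a single
provenance comment line (`# statelife <version> | config <hash> | seed
<seed>`); read them with `comment="#"`. Configs and reports are YAML/JSON.
Ages are in years; episode times are years since age 50; states are 1–4
(number of complications, 4 = three or more) with 5 = death.

## cohort.csv — one row per individual

| column | type | meaning |
|---|---|---|
| id | int | unique key |
| sex | `male`/`female` | |
| simd_quintile | int 1–5 | 1 = most deprived, 5 = least |
| entry_age | float | age at study entry (≥ 50) |
| exit_age | float | age at death or censoring (> entry_age) |
| exit_reason | `death`/`censored` | |
| onset_retinopathy_maculopathy, onset_cvd, onset_ckd, onset_diabetic_foot | float or empty | age at onset; empty = never observed |

## weight_sample.csv — auxiliary baseline sample (ages 45–54)

`id, sex, simd_quintile, age, state` — `state` is the complication count
state 1–4 at baseline.

## events.csv — generating truth event log (synthetic cohorts only)

`id, age, transition_id, complication` — continuous-time events;
`transition_id` 1/3/5 are the up-moves (complication named), 2/4/6/7 the
deaths (complication empty).

## panel.csv — 30-day slices

`id, slice_index, age_start, age_end, state, died_in_slice, sex,
simd_quintile` — `slice_index` is 0-based; the last slice may be shorter.

## episodes.csv — transition-specific at-risk intervals

`id, transition_id, from_state, t_entry, t_exit, status, sex,
simd_quintile` — one row per sojourn × allowed exit; `status` 1 marks the
realized exit, competing exits are censored (0) at the same `t_exit`.
Episode tables for the risk-factor models additionally carry `rf_<name>`
columns (uncentered values; centering happens at fit time).

## model_set.csv — fitted transition models

One row per transition × covariate: `transition, from_state, to_state,
covariate, hr, lo95, hi95, shape, rate, aic, n_events` (hazard ratios
with 95% Wald intervals; `rate` is the age-50 baseline hazard per year).

## weights.csv

`sex [, simd_quintile], w1..w4, n` — empirical start-state shares in the
[45, 55) window, summing to 1 per row.

## expectancies.csv

`sex, simd_quintile, total_le, le_state1..le_state4` — years; quintile
empty for sex-only strata. `expectancies_ci.csv` carries `quantity,
point, se, lo95, hi95` with quantity keys like `male_q1_total_le`.

## le_triangulation.csv

`stratum, a, b, le_a, le_b, abs_diff, rel_diff, flagged` — pairwise
comparison of multistate / chiang / two_state total LE.

## mortality_rates.csv

`age_lo, age_hi [, strata...], deaths, person_years, rate_per_1000py` —
rates suppressed (empty) below the person-years floor.

## manifest.json

Written by `run-all`: package version, config hash, seed, full pipeline
config, per-stage counts (individuals read, excluded short-followup,
excluded multi-jump, analyzed, events per transition), output file list.
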