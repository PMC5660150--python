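# CSV column dictionary

One row per control-arm comparison. UTF-8, comma-separated, `.` decimal, one
header row. Empty cells encode missing optional values (never 0). Booleans
are `true`/`false`.

## Outcome columns

| column      | type    | meaning |
|-------------|---------|---------|
| `study_id`  | text    | unique per (study, outcome); ties arms to mortality rows |
| `outcome`   | enum    | `IS_AAR`, `IS_LV` or `EF`; empty if the row carries only mortality counts |
| `mean`      | real    | raw mean outcome, percent in [0, 100] |
| `sd`        | real    | per-arm standard deviation (> 0 whenever `n_animals` > 1) |
| `n_animals` | integer | animals in the arm (≥ 1) |

## Moderators

| column | type | levels / unit |
|--------|------|---------------|
| `species` | enum | `dog`, `pig`, `sheep` |
| `strain`  | enum | `regular_pig`, `minipig`, `unreported` — pigs only, empty otherwise |
| `sex`     | enum | `male`, `female`, `both`, `unknown` |
| `occlusion` | enum | `permanent`, `temporary`, `unknown` |
| `vessel`  | enum | `LAD`, `LCX`, `LAD_LCX`, `RCA`, `unknown` |
| `approach` | enum | `open`, `closed`, `unknown` |
| `comedication` | bool | clinical MI co-medication for the whole study |
| `immunosuppression` | bool | |
| `quantification` | text | measurement method label (`TTC`, `MRI`, `echo`, ...) |
| `follow_up_hours` | real | follow-up after MI, **hours** |
| `ischemia_minutes` | real | ischemia duration, **minutes**; only for `occlusion=temporary`, else empty |
| `quality_score` | integer | study-quality checklist points (≥ 0) |
| `weight_kg` | real | optional, empty if unreported |
| `age_weeks` | real | optional, empty if unreported |
| `vf_excluded_untreated` | bool | animals fibrillating during induction were excluded without treatment attempt (sensitivity-analysis flag) |

Follow-up is stored in hours and ischemia in minutes so that regression
coefficients read directly as points/hour and points/minute. `unknown` /
`unreported` are first-class levels, analyzed as their own categories.

## Mortality columns (all optional)

| column | meaning |
|--------|---------|
| `peri_deaths`, `peri_total` | deaths / total during infarct induction |
| `peri_deaths2`, `peri_total2` | optional second sequential measurement |
| `post_deaths`, `post_total` | deaths / total after the procedure |
| `post_deaths2`, `post_total2` | optional second sequential measurement |

A non-empty `*_total` creates a mortality record for that phase; second-stage
pairs are combined as 1 − p_total = (1 − p₁)(1 − p₂) with effective n
(n₁ + n₂)/2.
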