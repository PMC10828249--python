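# CSV column dictionary

## Survey table (long format, one row per person-wave; empty cell = missing)

| column | type | meaning |
|---|---|---|
| `subject_id` | string | opaque subject identifier, stable across waves |
| `country` | string | ISO-3166 alpha-2 country code |
| `wave` | int 1–8 | biennial survey wave |
| `survey_year` | int | calendar year of the interview |
| `reported_age` | int | age reported at interview (first-priority age source) |
| `age_in_survey_year` | int | age in the survey year (second priority) |
| `birth_date`, `survey_date` | ISO date | used for the completed-years fallback |
| `gender` | `female`/`male` | required for inclusion |
| `education_years` | int ≥ 0 | years of education (carried forward within subject) |
| `self_perceived_health` | int 1–5 | US-version item, 1 = best … 5 = worst |
| `living_with_partner` | `alone`/`with_partner`/`unknown` | living arrangement |
| `osteoporosis_drugs` | 0/1 | auxiliary for index-method imputation |
| `gdp_kEUR` | float | country GDP/capita joined onto rows (synthetic tables) |

Instrument items: `grip_strength` (kg; or `grip_left`/`grip_right`),
`fatigue`, `appetite_loss`, `eating_less`, `difficulty_climbing_stairs`,
`difficulty_walking_100m`, `low_activity` (binary 0/1).

Index items: one column per catalog item name (binary 0/1), plus
`rheumatoid_arthritis`/`osteoarthritis` feeding the arthritis composite and
`self_perceived_health` (ordinal). See
`src/frailty_atlas/data/deficit_catalog.yaml`.

## Country attributes

Wide layout: `country,name,share_participant,gdp_kEUR,gdp_kEUR_ppp`
(GDP in thousand EUR, mean 2000–2004; `share_participant` marks the 29
countries with survey data). Long layout: `country,year,gdp_eur`
(+ optional `ppp_factor`); the loader averages 2000–2004 itself.

## Atlas output (`atlas.csv`)

`country, iso2, share_participant, method, missing_approach, gdp_variant,
age_band, gender, n, n_frail, prev_obs, ci_low, ci_high, prev_pred,
gdp_kEUR` — observed columns are empty for prediction-only countries;
`prev_pred` is present on every row.
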