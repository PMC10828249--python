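# frailty-atlas

Age- and gender-stratified frailty prevalence estimation and prediction for
European countries from SHARE-like survey data.

Frailty — the age-related loss of physiological reserve that turns minor
stressors into major health declines — is measured here in two established
ways from biennial panel-survey interviews of adults aged 50+:

* **40-item frailty index (FI)**: each health deficit (activities of daily
  living, chronic diseases, other physical/mental deficits) is scored into
  [0, 1]; FI is the mean of the 40 scores and a respondent is *frail* when
  FI ≥ 0.25.
* **Weighted frailty instrument**: a gender-specific discrete factor score
  over five components (grip strength, fatigue, appetite loss/eating less,
  mobility difficulty, low physical activity) classified against
  gender-specific thresholds.

On top of the scorers, the package provides the full epidemiological
pipeline used to build a European "frailty atlas":

* eligibility and wave filtering, 5-year age bands, education carry-forward
  and quartiles, country GDP/capita preparation (mean 2000–2004, thousand
  EUR, market or PPP-adjusted);
* chained-equations multiple imputation (predictive mean matching for
  numeric items, logistic regression for binary items, m = 10 by default)
  for the missing-not-at-random item data typical of frailty surveys, plus
  complete-case analysis and missingness diagnostics;
* stratified prevalence with Clopper–Pearson exact confidence intervals,
  averaged over imputations;
* a mixed logistic model of the binary frailty state,

  logit P(frail) = β₀ + β_male·male + β_a + β_{a:male}·male
                 + (γ₀ + γ_a)·GDP + u_subject + v_country,

  with age-band (a) and gender fixed effects in interaction, a continuous
  GDP/capita effect per age band, and crossed random intercepts for subject
  (repeated waves) and country — fitted per imputed dataset and pooled with
  Rubin's rules;
* model-based prediction of prevalence for any (age band, gender,
  GDP/capita) cell, which extends the atlas to the 13 catalog countries
  without survey data;
* a synthetic-cohort generator whose frailty states follow the model above
  exactly (published coefficient sets as generator truth), with item
  rendering consistent with the scorers and missing-not-at-random injection
  — so the entire pipeline is testable without access to restricted survey
  microdata.

## Worked example

```python
import pandas as pd
import frailty_atlas as fa

coeffs = fa.coefficient_set("instrument_mi")   # published fixed effects
cells = pd.DataFrame({
    "gender":   ["female", "female", "male"],
    "age_band": ["50-54",  "75-79",  "75-79"],
    "gdp_kEUR": [8.0, 8.0, 30.0],
})
print(cells.assign(prev_pred=fa.predict_prevalence(coeffs, cells).round(4)))
```

```
gender age_band  gdp_kEUR  prev_pred
female    50-54       8.0     0.0390
female    75-79       8.0     0.2842
  male    75-79      30.0     0.0793
```

Reading: in a lower-income country (8 kEUR GDP/capita), predicted frailty
prevalence among women rises from 3.9% at ages 50–54 to 28.4% at 75–79;
for men of the same age in a high-income country (30 kEUR) it is 7.9% —
age, gender and national wealth all shape the predicted burden.

End-to-end on synthetic data (simulate → impute → score → prevalence →
fit → pool → predict → atlas):

```sh
frailty-atlas run --seed 1 --out artifacts/
```

writes `atlas.csv` with one row per country × age band × gender carrying
observed prevalence (with exact CI) where survey data exist and the model
prediction everywhere, `fit.json` with pooled coefficients, and a manifest.
Individual stages are available as `simulate`, `score`, `impute`, `fit`,
`predict` and `atlas` subcommands.

## Layout

* `frailty_atlas.data_model` — survey/country tables, filters, derived variables
* `frailty_atlas.index`, `frailty_atlas.instrument` — the two frailty scorers
* `frailty_atlas.imputation` — complete cases, chained MI, diagnostics
* `frailty_atlas.estimation` — `FrailtyGLMM` / results objects, exact CIs,
  Rubin pooling, prediction
* `frailty_atlas.synthetic` — cohort generator with truth ledger
* `frailty_atlas.atlas` — atlas assembly and pipeline orchestration
* `docs/methods.md` — model, assumptions, defaults and limitations;
  `docs/data_dictionary.md` — CSV column dictionary
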