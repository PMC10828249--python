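# Methods

This note documents the statistical content of the package: the scoring
rules, the imputation engine, the mixed model, the synthetic-data generator
that stands in for restricted survey microdata, and the numerical and design
choices made where the published description left them open.

## Frailty scoring

**Frailty index.** The deficit-accumulation index averages 40 item scores,
each in [0, 1]: binary deficits score 0/1, the 5-level (US-version)
self-perceived-health item scores 0, 0.25, 0.5, 0.75, 1 from best to worst,
and the arthritis item is an any-positive composite of the two dichotomised
arthritis questions (positive if either is positive; negative only when both
are observed negative; missing otherwise). Classification is frail iff
FI ≥ 0.25; the boundary counts as frail, following the printed "≥".

Completeness is strict: the FI is reported only when all 40 items are
scorable. The partial-denominator convention common elsewhere in the
deficit-accumulation literature (dividing by the number of observed items) is
deliberately not used, because missing items are handled by multiple
imputation or listwise deletion here; mixing the two would double-count the
missing-data mechanism. Two items (osteoporosis, breathlessness) are
unavailable from wave 5 onward, so records from waves 5/6/8 can never be
complete — which is why those waves enter only the multiply-imputed index
analyses and are excluded from the complete-case index analyses.

The full published 40-item list lives in a supplement that is not
redistributed; the shipped catalog reproduces the documented structure
(16 ADL / 10 chronic-disease / 14 other items and the four specially-handled
items above) with plausible placeholder names marked `synthetic: true`. The
scoring engine is entirely catalog-driven, so a transcribed list drops in
without code changes.

**Weighted instrument.** The five components are grip strength (kg; maximum
over available hand measurements — an assumption, conventional for
grip-based instruments), fatigue, appetite loss and/or eating less,
difficulty climbing stairs and/or walking 100 m, and low physical activity;
compound components use the same any-positive rule. The gender-specific
intercept, weights and frailty threshold are *data* (YAML), validated on
load and refused without a provenance note. The published weight set is not
redistributed; the shipped default is a constructed synthetic stand-in with
the correct signs and plausible magnitudes (file and provenance both say
so). A score on or beyond the threshold classifies frail (boundary
convention chosen here; the description is silent). An unweighted auxiliary
mode counts the five phenotype deficits (grip weakness below a gender
cutoff) with frailty at ≥ 3 of 5; it is clearly labelled non-canonical.

## Derived variables

Ages resolve from the first available source: reported age at interview, age
in the survey year, then survey date minus birth date in completed years
(floor — an assumption; the rounding convention is not stated). Records
without a resolvable age ≥ 50, with an excluded wave, or with unknown gender
are dropped. Age bands are closed-left/open-right 5-year bands 50–54 … 80–84
plus open-ended 85+, partitioning [50, ∞).

Education years are carried forward within subject (missing cells filled
from the most recent non-missing wave — tie-break chosen here; observed
values are never overwritten) and categorised by linear-interpolation sample
quartiles. GDP/capita is the arithmetic mean of available annual values in
2000–2004 in thousand EUR, with a warning rather than an error when window
years are missing (non-Eurostat countries have gaps); the PPP-adjusted
variant is consumed from the country-attributes file, not computed. The
shipped 42-country catalog (29 with survey data, 13 prediction-only)
carries approximate public GDP figures for demonstration; real analyses
should supply a prepared file.

## Missing data

Chained-equations multiple imputation with m = 10 completed datasets
(matching the published choice). Internals the publication does not specify
are fixed defaults here: 10 sweeps per chain, visit order by ascending
missingness count, PMM donor pool k = 5. Numeric columns use predictive mean
matching — linear regression on the predictor set, each missing entry drawn
uniformly from the k observed donors with closest predicted means — so
imputed values always lie in the observed support. Binary columns use a
ridge-stabilised Newton logistic fit (ℓ2 = 1e-4 guards separation) with
Bernoulli draws; a single observed class degenerates to a constant fill with
a warning. Observed cells are never modified. The chain is fully
reproducible from its seed.

Predictor sets follow the analysis design: age band, gender, education
years, self-perceived health and living arrangement as auxiliaries, plus the
method's own items (five components, or 40 index items and
osteoporosis-drug exposure). Items structurally absent in late waves are
imputed like any other missing item in MI runs. Where item-level chains
leave a record's 40-item set incomplete (possible when a column has no
observed donors at all), the frailty index is imputed directly as a single
continuous variable by PMM on the auxiliaries; donor membership keeps it in
[0, 1]. Classification is recomputed per completed dataset.

Missingness diagnostics report Pearson chi-square tests (no continuity
correction) of the complete-case indicator against age band and against
each item's observed deficit-positivity.

## Prevalence and the mixed model

Stratum prevalence is the mean over completed datasets of the per-dataset
rate; its 95% interval is Clopper–Pearson exact, computed from the averaged
frail count rounded half-up and the averaged denominator (the averaging
mechanics after imputation are a choice made here).

The core model is a logistic regression of the binary frailty state on
gender × age band (reference: female, 50–54) and GDP/capita × age band
(continuous, thousand EUR), with crossed random intercepts for subject and
country. Estimation delegates to lme4::glmer (Laplace approximation, bobyqa)
through a subprocess bridge; the package owns the design construction, term
naming, pooling, prediction and validation, and provides an
ordinary-logistic backend (random effects off) used as an independent oracle
in the σ = 0 equivalence test. Non-convergence is flagged, not raised; a
degenerate (single-class) outcome is an error. Per-imputation fits are
pooled with Rubin's rules (total variance T = W + (1 + 1/m)·B) with
Barnard–Rubin small-sample degrees of freedom when the complete-data sample
size is supplied.

Predictions invert the logit of the fixed-effect linear predictor with both
random intercepts at zero (conditional/median prediction). Whether the
published predictions marginalised over the country intercept is not stated;
the conditional prediction is the default here, and a Monte-Carlo
marginalisation over the estimated country variance is available behind
`marginal=True`. The two differ: averaging the inverse logit over a random
intercept pulls predictions toward 0.5.

Under the default instrument coefficient set, the total GDP slope γ₀ + γ_a
is most negative at ages 70–74 (−0.0433 per thousand EUR), the protective
association peaking in the eighth decade, and predictions fall strictly with
GDP in that band. Predicted prevalence rises across age bands at fixed
gender and GDP throughout the observed GDP range; at extreme GDP values
(≳ 34 kEUR) the fitted age × GDP interaction implies a marginal inversion
between the two youngest bands — a property of the published coefficients,
not of this implementation.

## Synthetic cohorts

The generator's defaults are the study conditions: 29 observed countries
with their catalog PPP GDP values, 150 subjects per country, two biennial
waves (ages advance with the calendar between waves; band membership is
recomputed), 44.5% male, age-band frequencies from the published cohort
table, and the published coefficient set as generator truth with
σ_subject = 1.0 and σ_country = 0.3 (no variance components are published;
these are stated assumptions). Generation is two-stage: the frailty state F
is drawn from the model (so the estimation model is exactly true for the
scored labels), then items are rendered conditional on F such that the
corresponding scorer reproduces F exactly — for the index by budgeting the
deficit count either side of the 10-of-40 boundary, for the instrument by
biased rejection sampling with a deterministic saturate-the-deficits
fallback. Subject intercepts are shared across a subject's waves; country
intercepts are crossed with subjects, as in the fitted model.

Missingness injection is item-level logistic: log-odds = base (−3.2) +
age-band offset (0 → 1.4 across bands) + 0.8 if the to-be-masked value is
deficit-positive. The publication reports only the directions (more
missingness at older ages and in deficit-positive respondents); these
magnitudes were chosen once as realistic (≈4–14% per item, higher when
positive) and produce the documented complete-case bias: complete-case
prevalence below the full-sample/MI prevalence in the oldest bands.

What the generator does **not** emulate: sampling weights, household
structure, attrition, between-item correlation beyond what the two-stage
construction induces, and country-level frailty patterns beyond the GDP
effect plus a random intercept. Passing tests therefore demonstrate
correctness of the pipeline under the stated model, not calibration to any
real country's prevalence.

## Parameter recovery and problem sizes

The recovery experiment (`frailty_atlas.recovery`) simulates the default
cohort (≈8,700 person-waves, 4,350 subjects), scores it completely, fits the
mixed model and compares every fixed effect with the generating value; the
acceptance criterion is agreement within two standard errors. At this design
size the binary outcome, the subject intercepts (two observations each) and
29 country-level GDP values leave substantial Monte-Carlo error — standard
errors around 0.6–0.8 for the age/gender terms and ≈0.04 for GDP
interactions — so recovered coefficients scatter correspondingly around
truth; the 2-SE criterion is the designed check. One such fit takes a few
minutes on one CPU; unit tests use smaller cohorts (hundreds of subjects)
and the σ = 0 oracle comparison uses 1,800 single-wave subjects.

## Known limitations

* The shipped instrument weights and part of the deficit catalog are
  synthetic stand-ins (clearly labelled); results with them are
  method-faithful but not numerically comparable to published instrument
  scores.
* The lme4 backend requires R on PATH; without it only the fixed-effects
  backend is available.
* PMM with small donor pools can understate imputation variance; k = 5 is a
  conventional compromise.
* The Laplace approximation is known to bias variance components for binary
  outcomes with few observations per cluster; the subject variance estimate
  should be read with that in mind.
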