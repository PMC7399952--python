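# meddsurvey

Design-based analysis of Mediterranean-diet (MedD) adherence and cognitive
performance in NHANES-like cohorts of US older adults.

## The problem

How closely do US adults aged 60+ follow a Mediterranean eating pattern, and
is closer adherence associated with better cognition? Answering this from a
national nutrition survey requires four ingredients that this package
implements end to end:

1. **Dietary scoring.** Two 24-h dietary recalls per participant, expressed
   as USDA Food Patterns Equivalents Database (FPED) food-group amounts, are
   averaged and scored with the 18-point literature-based MedD index: nine
   components (fruit, vegetables, legumes, cereals/whole grains, fish, meat,
   dairy, alcohol, olive oil), each scored 0/1/2,

   `S = Σ_{c=1}^{9} s_c,   s_c ∈ {0,1,2},   S ∈ [0,18]`.

   Fruit and vegetables use cup-equivalent rules (fruit: ≥1 CE → 1, ≥2 CE →
   2; vegetables: ≥0.5 CE → 1, ≥1 CE → 2), olive oil uses tablespoon cutoffs
   (≥14 g → 1, ≥28 g → 2), alcohol is unimodal (1 for <12 g, 2 for 12–24 g,
   0 for >24 g ethanol/day), and the remaining five components are graded
   against configurable gram cutoffs, with meat scored in the decreasing
   direction.
2. **Cognitive standardization.** Raw CERAD word-list (immediate and
   delayed), Animal Fluency and Digit Symbol scores are converted to
   z-scores within five education strata; a global composite averages the
   four z-scores (complete case); z < −1 flags "low performance".
3. **Survey inference.** All estimates respect the stratified multistage
   design: Horvitz–Thompson ratio means, Taylor-linearized (between-PSU)
   variances, survey-weighted OLS and logistic regression with sandwich
   covariances, Rao–Scott-corrected chi-squared tests, Tukey-adjusted
   pairwise contrasts, and weighted kernel smoothing. Pooled 2-year cycle
   weights are halved to 4-year analysis weights.
4. **Synthetic cohorts with known truth.** A generator emulates the survey's
   structures — informative selection weights, clustered design, zero-heavy
   intake distributions, education-dependent cognition, a tunable latent
   diet–cognition effect — so every estimator can be validated against a
   brute-force census oracle.

## Worked example

```python
import meddsurvey as m

cfg = m.AnalysisConfig(simulate=m.CohortConfig(n_participants=3000, seed=7))
tables = m.run_full_analysis(cfg)

df = tables.analysis_frame
design = m.SurveyDesign(df.SDMVSTRA, df.SDMVPSU, df.WT4YR)
est = m.svy_mean(df.SCORE_TOTAL.astype(float), design)
sd = m.svy_sd(df.SCORE_TOTAL.astype(float), design)
print(f"mean {est.estimate:.2f} (95% CI {est.ci_low:.2f}-{est.ci_high:.2f}), SD {sd.estimate:.2f}")
```

prints

```
mean 5.17 (95% CI 5.06-5.29), SD 2.34
```

— the survey-weighted population mean adherence score (the generator's
census truth for this configuration is 5.15, so the weighted estimator
recovers it within its CI; about 29% of the 18-point maximum, i.e. older
adults in the emulated population do not follow a Mediterranean pattern).
The fitted models live in tidy tables; for the global cognitive composite:

```
>>> tables.ols_models.query("measure == 'Global Cognition'")
         measure   model   beta     se  ci_low  ci_high   p    n
Global Cognition Model 1 0.0330 0.0050  0.0222   0.0439 0.0 2996
Global Cognition Model 2 0.0358 0.0057  0.0237   0.0479 0.0 2756

>>> tables.logistic_or.query("measure == 'Global Cognition'")
         measure tertile    or  ci_low  ci_high     p    n
Global Cognition  middle 0.315   0.151    0.655 0.004 2756
Global Cognition highest 0.264   0.089    0.778 0.019 2756
```

Model 1 regresses the education-standardized composite on the continuous
MedD score alone; Model 2 adds the 11 covariates (age, sex, BMI,
race/ethnicity, income-to-poverty ratio, marital status, smoking, diabetes,
CVD, hypertension, stroke). The odds ratios compare low-cognition risk in
the middle/highest adherence tertiles against the lowest; with the default
planted diet effect, higher adherence is protective (OR < 1). Per-model n
drops below the cohort size because of missing covariates and cognitive
tests (complete-case within each model).

A command-line interface wraps the same pipeline:

```bash
meddsurvey simulate --out sim/ --seed 7
meddsurvey score --recalls sim/recalls.csv --out scores.csv
meddsurvey analyze --config cfg.yaml --out results/
meddsurvey sensitivity --config cfg.yaml --out results/
```

`analyze` writes one CSV per result table (descriptives, component scores by
tertile, OLS models, logistic odds ratios, the no-memory-complaint
sensitivity refit with freshly computed tertiles, and demographic mean-score
comparisons with Tukey-adjusted p-values) plus a JSON manifest with sample
sizes and exclusion counts.

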