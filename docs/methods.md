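# Methods

This note documents the models, conventions and numerical choices behind
meddsurvey, and what the synthetic-cohort validation does and does not show.

## Dietary scoring

Intakes are ingested one recall day per row and averaged arithmetically over
the two days; participants without both days are excluded (completing two
recalls is an inclusion requirement, applied before any other exclusion).
Energy plausibility is screened with the Iglewicz–Hoaglin modified z-score
`0.6745 (x − median) / MAD` at the conventional |z| ≥ 3.5 cutoff; the screen
partitions the cohort exactly and, like the population it emulates, flags
nobody unless implausible records are planted.

The nine MedD components are sums of their FPED constituents (vegetables sum
exactly the four FPED vegetable groups listed in the component map; fruit
juice is not part of fruit; cereals is whole grains only). Alcohol is
carried in grams of ethanol; a drink-equivalents column is accepted with a
configurable 14 g/drink conversion. Olive-oil grams are a directly supplied
per-participant amount — item-level food-code extraction is out of scope.

Scoring rules: the fruit/vegetable/olive-oil rules are fixed (printed
cut-points with thresholds inclusive upward, i.e. `≥`); alcohol scores 1
below 12 g, 2 on the closed interval [12, 24] g (12 g exactly falls in the
moderate band) and 0 above 24 g. The five graded components use configurable
gram cutoffs defaulting to a serving-based literature index converted to
g/day: legumes 10/20, cereals 130/195 (a score of 1 requires roughly 4.5 oz
of whole grains), fish 14/36, meat 80/120 decreasing, dairy 200/400. The
cutoff config is the single source of truth; tests pin the defaults.

Adherence tertiles are equal-size by construction: stable sort by
(score, participant id), then cut into contiguous groups whose sizes differ
by at most one with the remainder given to the lower groups (3068 → 
1023/1023/1022). Ties at a cut point are split deterministically by the
sort, so reruns agree exactly; the tertile variable is therefore a function
of the whole sample, not of the score alone.

## Cognitive standardization

Standardization is an unweighted cohort transformation using the sample SD
(n−1): within each of five education strata every test is centered and
scaled to mean 0, SD 1 (tolerance 1e−9 in tests). Survey weights enter at
estimation, not standardization. The global composite is the mean of the
four test z-scores and requires all four (complete case), which is why its
sample size is smaller than any single test's. "Low performance" is the
strict rule z < −1; z = −1 exactly is not low. Missing test scores stay
missing and drop the participant only from that measure's models.

## Survey estimation

All estimators assume a stratified multistage with-replacement design
(strata, PSUs, positive weights). Variances come from Taylor linearization:
every estimator's per-record influence contributions are summed to PSU
totals and the between-PSU covariance within strata, scaled by
n_h/(n_h − 1), is accumulated. Excluded records (missing response,
covariates, or domain membership) keep their place in the design and
contribute zero influence — domain estimation rather than design subsetting.
Inference uses t/F references with design df = #PSUs − #strata. Lonely PSUs
(single-PSU strata) raise by default; the `centered` policy uses the
deviation from the grand mean PSU total instead.

* Weighted mean/proportion/SD: Horvitz–Thompson ratio estimators; the SD's
  SE combines the linearized variance of the weighted variance with a delta
  step (the plug-in mean contributes no first-order term).
* OLS: `β = (XᵀWX)⁻¹XᵀWy` with the linearized sandwich on `w_i x_i e_i`.
* Logistic: weighted pseudo-maximum-likelihood via step-halved Newton
  starting at β = 0, relative log-likelihood tolerance 1e−10, max 50
  iterations; sandwich on `w_i x_i (y_i − p_i)`. Perfect classification
  raises a separation error; non-convergence raises with diagnostics.
  Odds ratios are exponentiated coefficients and CI bounds.
* Chi-squared: Pearson X² on weighted cell proportions, corrected by the
  Rao–Scott generalized design effects, computed exactly as the eigenvalues
  of the linearized covariance of the independence residuals relative to
  the multinomial covariance at the observed proportions (a generalized
  eigenproblem; the (m−1)-denominator convention makes every eigenvalue
  exactly 1 under equal-weight SRS, so the statistic reduces to classical
  Pearson). The p-value uses the second-order Satterthwaite correction,
  X²/(δ̄(1+a²)) against χ² with df1/(1+a²) degrees of freedom. In a
  1000-replicate null calibration under the default generator this keeps
  type-I error near nominal for 2×3 through 5×3 tables; calibration
  degrades toward conservatism as the table df approaches the design df
  (e.g. 6-level factors against only 14 design df), a known limitation of
  design-corrected chi-squared tests with few PSUs.
* Tukey contrasts: all pairwise differences from a cell-means weighted OLS;
  adjusted p refers |t|√2 to the studentized range with k groups and the
  design df, so k = 2 reduces exactly to the unadjusted two-sided t test.
* Kernel smoothing: weighted Nadaraya–Watson with a Gaussian kernel;
  default bandwidth is Silverman's rule on weighted x with Kish effective
  n. Grid points with numerically zero kernel mass return NaN.

Weight-rescaling invariance holds exactly for means, proportions, SDs,
regression coefficients and their linearized SEs; totals scale, as they
must.

## Analysis pipeline

Stages run in fixed order: recall validation → exclusion cascade
(incomplete recall pair, then no cognitive test at all, then the energy
screen) → averaging → component mapping → scoring → tertiles → education
z-scores → estimation. Model 1 is the MedD score alone; Model 2 adds the 11
covariates (categoricals one-hot with the first category as reference; age,
BMI and income ratio continuous). Education acts only through
standardization and is not a model covariate. Logistic models use the
lowest tertile as reference. The sensitivity analysis filters to
participants without memory complaints and recomputes tertiles within the
subset — fresh cut points, not the full-cohort boundaries — before
refitting. Outputs are deterministic for a fixed config and seed; the
manifest records per-model complete-case sample sizes and exclusion counts.

## Synthetic cohort generator

A latent diet-quality factor θ ~ N(0,1) per participant (2% of its variance
shared within PSU) drives:

* **Intakes.** Gamma families for continuous amounts (fruit, vegetables,
  whole grains, meat, dairy) with a mean-corrected log-location shift
  `exp(αθ − α²/2)`; Bernoulli×lognormal for the zero-heavy components
  (legumes, fish, olive oil, alcohol), with the any-consumption odds also
  rising in θ. Meat loads negatively; alcohol is moderation-seeking (its
  consumption median moves toward 18 g as θ rises, matching the unimodal
  scoring rule). Day-to-day variation is multiplicative lognormal
  (σ = 0.35, mean 1, configurable); consumers report on both days.
  Defaults were calibrated once so the census component-score means match
  the magnitudes reported for US older adults (total ≈ 5.2/18, olive-oil
  consumption ≈ 3%) and were not revisited.
* **Cognition.** Per-test latent z = γθ + √(1−γ²)ε with γ =
  `diet_effect_gamma` (default 0.12 per test, chosen so the OLS slope of
  cognitive z on MedD points is ≈ 0.05); raw scores are truncated/rounded
  to instrument scales (CERAD words 0–10 per trial, DSST 0–133, AFT ≥ 0)
  around education-dependent means.
* **Design.** Participants are allocated evenly to strata and two PSUs per
  stratum; candidates are drawn from the superpopulation and accepted with
  a logistic selection propensity whose logit correlates with θ at
  `selection_informativeness`; weights are inverse propensities (stored on
  the 2-year scale and halved downstream), so the Horvitz–Thompson ratio
  mean is consistent for superpopulation means. Energy is bounded
  (truncated person-level normal, bounded day noise) so the modified-z
  screen flags nothing unless `outlier_energy_count` records are planted at
  20× the median.
* **The rest.** Covariates follow the emulated cohort's marginals and are
  missing completely at random at configurable rates (defaults: income
  ratio 8%, marital 0.1%, education 0.13%); memory complaints (default
  rate 16%) are negatively related to the latent cognitive level.

`true_population_summary` computes census values (mean/SD of the total
score, component amount and score means, score–cognition correlations) by
brute force on 100k weight-free superpopulation draws; the stream is fixed,
so the oracle is deterministic per configuration and cached.

What the generator does **not** emulate: nonresponse adjustment and raking,
item-level food codes, measurement error beyond lognormal day noise,
correlated covariate missingness, or education–diet confounding (education
and θ are independent, so passing tests show estimator correctness, not
robustness to confounding structures absent from the generator).

## Validation sizes and numerical choices

Confidence-interval coverage (weighted mean against the census oracle; OLS
slope and logistic log-OR against effects planted on generated cohorts) is
measured on 200 replicates at n = 3000; null test calibration on 1000
replicates at n = 1200 with the diet effect switched off. Unit-level
property tests use smaller replicate counts. The Rao–Wu stratified PSU
bootstrap (n_h − 1 resamples, weights rescaled by n_h/(n_h − 1)) is the SE
oracle; a naive n_h-of-n_h bootstrap would understate between-PSU variance
by (n_h − 1)/n_h. Degenerate inputs fail loudly: zero-MAD energy screens,
constant or tiny education strata, rank-deficient design matrices (the
offending columns are named), lonely PSUs under the default policy, and
non-positive weights all raise typed errors.
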