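# Methods

This note documents the statistical model behind `cadpipe`, the design of
the synthetic cohort generator, the numerical conventions, and the known
limitations — the choices a maintainer or reviewer would want spelled out.

## 1. Biomarker classification

A/T/N status is determined from CSF markers with fixed cutoffs: amyloid
positivity (A+) iff Aβ42 **< 580 pg/mL** (the assay-validated 550 pg/mL
threshold widened by a 5% confidence margin; 550 is available via
`BiomarkerCutoffs(abeta_pos_below=550)`), tau pathology (T+) iff p-tau
**> 61 pg/mL**, neurodegeneration (N+) iff t-tau **> 350 pg/mL**. Vascular
positivity (V+) iff Fazekas score **≥ 2** or **≥ 4** cerebral microbleeds.
Each printed inequality is applied literally, so boundary values
(Aβ42 = 580, Fazekas = 1 with 3 CMBs) are negative for A and V
respectively.

Analysis groups: reference `CUA-V-` (A−T−N− and V−), amyloid `CUA+` (A+
and V−, irrespective of T/N), vascular `CUV+` (V+ with A−T−N−). The three
groups are mutually exclusive but not exhaustive: combined-pathology
profiles (e.g. A+V+) and isolated T+/N+ land in `other`, as do records
flagged with cortical superficial siderosis or established ischemic
lesions (exclusion criteria, not V+ contributions). Records with missing
required markers are `unclassifiable`. One deliberate convention: a single
*positive* MRI rating is conclusive for V+ even if the other rating is
missing, but a single negative one cannot establish V−.

## 2. Feature selection

Within the reference group, each candidate score's Pearson r with
chronological age is computed on pairwise-complete observations, with the
two-sided p from the t transform of r. Features with raw p < α/m survive
(Bonferroni; m defaults to the number of candidates, i.e. one family).
Survivors are scanned in descending |r| (ties broken by input order) and a
feature is discarded if its |ρ| with any already-kept feature exceeds 0.7.
The greedy descending-|r| rule operationalizes "prioritize the highest
correlations"; genuine domain-coverage judgments cannot be automated, so a
`must_keep` config list lets users pin features through the collinearity
filter.

## 3. Education correction

Neuropsychological scores are strongly education-dependent, and leaving
that dependence in the features would leak education into every downstream
association. Each selected score X is therefore regressed on years of
education (simple OLS, closed form) within the reference group, and
replaced by its residual re-centred on the original mean:

    X_corrected = X̄ + (X − X̂),   X̂ = â + b̂·education

This preserves the score's scale and range, reproduces X̄ exactly as the
corrected in-sample mean, and makes the corrected score orthogonal to
education in the fitting sample. The correction is **fitted on the
reference group only** and applied unchanged to all groups, so pathology
groups cannot distort the normative education effect. Sex and APOE ε4 load
are *not* residualized by default — diagnostic GLMs of CAD on education,
sex and APOE typically find only the education effect — but a config flag
(`residualize_sex_apoe`) exposes the extended correction. Rows with
missing education cannot be corrected; their features are set missing and
the rows drop out at modeling time.

## 4. Cognitive age model and bias correction

The model is a feature scaler plus an ordinary (unregularized) linear
regression of chronological age on the corrected scores, fitted on the
reference group by minimizing MSE. The scaler (per-feature mean/SD) is
estimated once on the full fit sample and reused across folds; the
leakage through a per-feature mean at n = 140 is negligible, and a
per-fold scaler is available via `scale_per_fold`. A shuffled,
seed-controlled 5-fold split yields out-of-fold predictions for every fit
row and per-fold MSE; the final coefficients are refit on the full sample
(they equal the normal-equation solution, which the tests assert to 1e-8).

Age-prediction models overpredict young and underpredict old ages — a
regression-to-the-mean artifact. The bias is estimated by simple OLS of
the **out-of-fold** delta (ŷ_raw − y) on y; out-of-fold predictions are
used because in-sample deltas are optimistically small and would
underestimate the bias. The fitted line (a·y + b) is subtracted from
ŷ_raw, giving the bias-corrected prediction and

    CAD = ŷ_corrected − y.

By OLS residual identities, the corrected out-of-fold deltas of the fit
sample have exactly zero mean and zero slope against age. This correction
requires the participant's chronological age at prediction time, which CAD
always has; the alternative inversion scheme (regress ŷ on y and invert
the line) is available via `bias_mode="inverse"`. The fitted model — 
feature order, scaler, coefficients, bias line, CV record — serializes to
JSON and is applied identically to all groups.

## 5. Group comparisons and associations

CAD distributions across the three groups are compared with tie-corrected
Kruskal–Wallis tests (χ² reference with k−1 df; the degenerate all-equal
case returns H = 0, p = 1 by convention).

Associations are GLMs `CAD ~ factor` per clinical group. **CAD stays in
years; predictors are z-scored** (sample SD, ddof = 1), so β reads as
delta-years of cognitive age per SD of the factor — binary factors are
0/1-coded and z-scored like everything else for uniformity. p-values are
two-sided t-tests; CIs are 95% t quantiles. Factors are analyzed in small
groups (cognitive reserve, sedentarism/physical activity, tobacco/alcohol,
diet, sleep), and Benjamini–Hochberg FDR is applied within each
(clinical group × factor group) family — grouping keeps a modest-n study
from drowning every effect in one giant correction. Factors significant
post-FDR are re-fitted with sex, APOE ε4 load and years of education as
z-scored covariates (sensitivity models); these inherit the univariate FDR
decision and report raw p. CSF-marker associations run through the same
code path with those covariates always included. Models are complete-case;
degenerate factors (constant within a small group) are skipped with a
warning and do not count toward the family size.

## 6. Synthetic cohort generator

The generator emulates the cohort the analysis expects, with defaults
fixed once as the study conditions:

- **Groups**: 140 reference / 23 amyloid / 14 vascular participants.
- **Ages**: uniform on 40–80 years; the pathology groups' lower bound is
  raised by 10 years, shifting their means ≈ +5 years — reproducing the
  age confound the bias correction must tolerate.
- **Demographics**: 55% female; years of education discrete on 8–20
  (median 14, IQR ≈ 12–16); APOE ε4 load multinomial with carrier
  enrichment in the amyloid group (48% vs 21% carriers).
- **Biomarkers**: drawn strictly on the requested side of every cutoff
  (fixed offset + half-normal spread, clipped away from zero), so the
  classifier reproduces the requested labels for 100% of rows by
  construction. A configurable fraction of the amyloid group is
  additionally T+ (30%) / N+ (20%), exercising the "A+ irrespective of
  T/N" rule.
- **Scores**: each of the 12 battery tests is an affine function of age
  and education plus Gaussian noise. Slopes and intercepts resemble the
  real instruments (e.g. Digit Symbol-Coding ≈ −0.55 points/year, TMT-B ≈
  +1.2 s/year); noise SDs give per-test age-equivalent noise of ~11–25
  years, so the pooled battery predicts age with a cross-validated RMSE of
  ≈ 4 years — a realistic regime for a multidomain battery.
- **Covariates**: ten lifestyle/reserve variables (vocabulary, reserve
  questionnaires, sitting hours, physical activity, smoking, alcohol,
  diet, sleep quality), all null by default. A planted effect acts
  *through the scores*: affected rows' test scores are shifted by
  `age_slope × (planted_cad_effect × z(covariate))`, i.e. the participant
  performs like someone that many years older. Recovery therefore
  exercises the entire pipeline, not just the final GLM.

Determinism: one `numpy` Generator seeded from the spec drives all draws
in a fixed order, so a fixed seed yields a byte-identical table.
Missingness (`inject_missingness`) is completely at random — one blanked
feature in each of n randomly chosen rows — mirroring the handful of
exclusions real studies report without claiming a mechanism.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: non-linear age trajectories, floor/ceiling
effects and discreteness of real test scores, correlated residuals beyond
the shared age/education signal, informative missingness, practice
effects, and any true group difference in CAD. Null-centered CAD across
groups is a property of the generator, not evidence about any cohort.

Parameter recovery is attenuated by design, not by accident: the planted
shift enters the features collinearly with age, so the age model absorbs
part of it exactly as measurement error attenuates any errors-in-variables
regression. At the default noise level the theoretical attenuation factor
is ≈ 0.88, and the recovered mean β for a planted −1.5 delta-years/SD
effect sits near −1.25 — a property worth knowing when interpreting real
CAD association magnitudes, and documented rather than hidden by tuning
the generator noiseless.

## 7. Numerical conventions and degenerate inputs

- Simple regressions (education correction, bias line) use the closed-form
  covariance/variance solution; the multivariate age model uses
  scikit-learn's least squares and is asserted against explicit normal
  equations; association inference uses statsmodels OLS and is asserted
  against hand-computed t statistics.
- Missing values are NaN/None throughout; no sentinel numbers.
- Zero education variance, zero age variance, constant factors/features,
  rank-deficient designs (named collinear columns) and too-few-rows
  conditions all raise informative `ValueError`s rather than producing
  silent garbage.
- Bonferroni and greedy tie-breaks: input order decides ties in |r|.
- BH-FDR is the standard step-up with monotone enforcement, capped at 1.
- All stochastic components (generator, fold assignment) are seeded; the
  CLI chain is byte-reproducible for fixed seeds.

## 8. Problem sizes used in the test and acceptance runs

The suite exercises cohorts of 177 rows (the default group sizes).
Replicated experiments use 50 replicate cohorts for parameter recovery and
null-β centering, 400 replicate group analyses for the type-I error check,
and 100 seeded cohorts for classification consistency; the acceptance
script uses 25 cohorts × 8 factors for the null rejection rate and 30
replicates for planted-effect recovery. These sizes give standard errors
comfortably inside the asserted bands while keeping a full run in well
under a minute of CPU.

## 9. Known limitations

- Cross-sectional only; no longitudinal CAD change or mixed models.
- No interaction models (e.g. sex × pathology) and no mediation analysis.
- The domain-coverage aspect of feature curation is a human judgment; the
  code only automates the correlation screen and the collinearity cap.
- The education correction is linear; strongly non-linear education
  effects would leave residual confounding.
- At small group sizes (n ≈ 14–23) the association GLMs are honest but
  underpowered — the pipeline demonstrates this itself in its
  planted-effect experiments.
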