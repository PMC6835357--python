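# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of the `dietmet` pipeline. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed by the pipeline

A parallel two-arm dietary intervention: 42 participants, 24 randomized
from habitual Western-leaning diets to a Prudent diet ("W-P") and 18 to a
Western diet ("P-W"), with paired samples at baseline and week 2 in two
biofluid matrices (fasting plasma, single-spot urine). Acquisition follows a
serial-injection format: each run holds the baseline/week-2 pairs of three
participants plus one pooled QC (7 injections), with participant order
randomized across runs. Self-reported nutrient records cover 20
micro/macronutrient categories for both periods.

## Data model and missingness

Responses are non-negative peak areas; *missing* (below detection limit /
not detected) is distinct from a measured zero, encoded as an empty cell on
disk and NaN in memory. An import option `zeros_as_missing` reinterprets
exported zeros as missing for data produced under the convention that
conflates the two. All on-disk numbers use a fixed `%.17g` format so I/O
round-trips are byte-stable.

## Preprocessing stages and their order

1. **Internal-standard normalization** (both matrices): every response is
   divided by the sample's spiked-standard response, removing per-injection
   efficiency variation. Precondition: the standard is positive in every
   sample.
2. **Creatinine normalization** (urine): division by per-sample creatinine
   cancels the hydration/dilution factor of spot urine.
3. **Detection filter**: feature kept when measured (non-missing) in a
   fraction ≥ `detection_fraction_min` (default 0.75) of *non-QC* samples.
   The boundary is inclusive so a feature at exactly 75% survives; QC
   samples are excluded from the denominator.
4. **QC-precision filter**: feature kept when the CV (sample SD over mean,
   ddof 1) of its non-missing QC responses is strictly < `qc_cv_max`
   (default 0.30). CVs are computed on normalized, untransformed responses —
   the scale on which instrument precision is quoted. Features with < 2 QC
   observations have undefined CV and are retained with a warning.
5. **Half-minimum imputation**: each missing value is replaced by half the
   feature's smallest observed response; observed cells never change.
6. **Batch correction** (urine by default; plasma drift is typically within
   the internal standard's reach and correction is skipped): see below.
7. **glog transform** `x → log2((x + √(x² + λ²))/2)`; `λ = "auto"` uses the
   smallest positive response in the table, `λ = 0` reduces to log2. The
   transform is strictly monotone and variance-stabilizing near zero.
8. **Autoscaling**: per-feature centering and unit variance (ddof 1);
   constant features are flagged and excluded from multivariate models.

Paired week2/baseline **response ratios** are formed per participant from
the imputed, batch-corrected, *untransformed* responses; the ratio table is
then glog-transformed and autoscaled for OPLS-DA. This order is the only
one in which every stage's preconditions (positivity, completeness) hold.
Imputation precedes batch correction so the log-scale model sees complete
data.

## Batch correction

Batch = run (one QC per 7-injection run). On the natural-log scale, each
batch's anchor mean (QC samples in `qc` mode; all samples in `grand-mean`
mode) is shrunk toward the cross-batch prior by precision weighting:

    posterior_b = (n_b/σ² · m_b + 1/τ² · μ) / (n_b/σ² + 1/τ²)

with σ² the pooled within-batch anchor variance and τ² a method-of-moments
estimate of the between-batch variance (`Var_b(m_b) − σ²·mean(1/n_b)`,
floored at 1e-12). The correction subtracts `posterior_b − μ` from every
sample in batch b. Two limits matter in practice:

* with a **single anchor per batch** (the default design) σ² is not
  estimable and the posterior is the batch mean itself — each batch is
  pinned to its QC, which removes drift exactly at the QC positions and to
  first order between them;
* `shrink=False` forces τ² → ∞, the limit in which a pure location shift
  between batches is removed exactly (verified to 1e-8 in the tests).

The fitted model is invertible (apply-then-invert is identity to 1e-10).
Scale (variance) correction is off by default: one QC per run cannot
estimate within-run scale.

## Statistical models

**Volcano.** Per feature, `fc` is the ratio of geometric-mean paired ratios
(W-P over P-W); p comes from a pooled-variance two-sample t-test on
glog-transformed ratios; q from Benjamini–Hochberg step-up. A feature is
"volcano-significant" when fc lies outside [1/1.3, 1.3] *and* p < 0.05; the
robust-call rule uses the stricter q < 0.05.

**OPLS-DA.** Single-response orthogonal PLS: `n_orth` (default 1)
orthogonal-signal-correction deflations followed by one predictive
component. With one response the NIPALS solution is closed-form
(w ∝ X′y), so no iteration is needed; `n_orth = 0` reduces exactly to
single-component PLS-DA. R²Y is the fitted explained class variance; Q²
comes from stratified k-fold cross-validation (default 7 folds, fold models
refit without the held-out fold). The permutation p-value is
`(1 + #{permuted Q² ≥ observed Q²})/(n_perm + 1)` with n_perm = 1000 by
default. Q², not R², is permuted: cross-validated predictivity is the
robustness claim being tested. Each permutation recomputes the *entire*
statistic, including fold stratification from the permuted labels —
stratifying on the observed labels only would break exchangeability and
makes the test severely conservative (we measured a null rejection rate of
0 before adopting this). S-plot coordinates are cov(x_j, t) and
corr(x_j, t) against the predictive score.

**Moderated Hotelling T² (time-course ranking).** Per feature, participants
contribute (baseline, week2) profiles; with d the between-arm difference of
mean profiles and S the pooled within-arm profile covariance,

    S̃ = (n_pooled·S + ν·S₀) / (n_pooled + ν),   n_pooled = n₁ + n₂ − 2,
    T² = (n₁n₂/(n₁+n₂)) · d′ S̃⁻¹ d,

where S₀ = diag(median over features of the pooled variances) is the
cross-feature prior and ν (`meba_prior_df`, default 3) its weight. ν = 0 is
the classical two-sample Hotelling statistic, verified against longhand
matrix arithmetic on random instances to 1e-8; this anchor, not equation-
level fidelity to any particular published empirical-Bayes time-course
estimator, is what the implementation claims. Features are ranked by T²
descending with lexicographic tie-breaks. A pass/fail p-value is attached
through the classical T² → F mapping with p = 2 dimensions; it is exact at
ν = 0 and slightly conservative at ν = 3 (measured null pass rate 0.037 at
α = 0.05), which the robust-call rule tolerates. Zero mean-profile
difference returns T² = 0 without inverting S̃ (the statistic's value
regardless of covariance), so degenerate fixtures behave; a singular S̃
with non-zero d raises.

**Mixed ANOVA (diet × time).** With exactly two timepoints the
repeated-measures interaction equals the between-arm test on within-subject
differences, so Δ = week2 − baseline (glog scale) is regressed on
arm + age + sex(M=1) + BMI and the partial F for arm (df1 = 1) is reported.
The equivalence F = t² in the covariate-free balanced case is tested to
1e-8, and the covariate case is cross-checked against an independent OLS
fit. Collinear designs raise with the offending columns named.

**Partial correlation.** x and y are residualized on the covariates (with
intercept) by least squares after listwise deletion; r is the Pearson
correlation of residuals and p comes from `t = r·√((n−2−k)/(1−r²))` with
df = n−2−k. Zero-variance residuals yield an explicitly flagged undefined
result. A QR-based matrix version computes all feature × nutrient pairs at
once and agrees with the scalar routine to 1e-10.

**ROC.** AUC by the Mann–Whitney identity (ties ½) with the
normal-approximation two-sided p; sensitivity/specificity at the
Youden-optimal threshold (marker ≥ threshold calls the positive class).
Ratiometric markers are ratios of untransformed responses.

**Robust-biomarker rule.** Passes-of-3 counts the moderated-T² p, the
interaction p, and the volcano q against α/q-threshold 0.05; robust requires
≥ `n_models_min` (default 2) model passes and ≥ `n_nutrient_min` (default
2) nutrient correlations with |r| > 0.30 and p < 0.05. The rule is monotone
(lowering a p or raising an |r| can never lose a call) and reports the top
five nutrient correlations by |r| with signs.

## Synthetic study generator

Abundances are log-normal; a CV maps to the log scale via
σ² = ln(1 + CV²). Per feature and participant the log response decomposes
into feature mean (spread 1.0 around ln 500), between-subject biological
deviation (CV 0.45 plasma / 0.70 urine), week-to-week within-subject
deviation (CV 0.25), per-injection efficiency shared by all features of a
sample (CV 0.08, removed by the internal standard whose own technical CV is
0.03), urine hydration dilution shared with creatinine (CV 0.40, removed by
creatinine normalization; creatinine technical CV 0.04), and per-cell
technical noise (CV 0.10). With this decomposition the normalized QC CVs
have a median near 0.10–0.11, inside the 4–12% precision band such
instruments report, and the normalized urine biological CV lands near 0.8.

Planted diet-responsive features (default 6 per matrix, fold changes
1.5–5, four Prudent-responsive and two Western-responsive) have their
week-2 responses multiplied by the fold change in the responding arm only.
Each participant carries a latent diet-shift intensity z ~ N(0,1):
nutrient-record deltas load on ±z with coefficient 0.85 (two
anti-correlated Prudent/Western blocks, within-block |r| ≈ 0.72), and
planted features' individual response magnitudes couple to z with
correlation `nutrient_effect_r` (default 0.5) and spread 0.30 log units.
Arm-level delta means and SDs for all 20 categories are the intervention's
published summary table, taken as generator inputs; per-day and
per-2000 kcal units are treated as numerically equal (cohort mean intake
≈ 1940 kcal/day). Baseline intakes describe a Western-leaning free-living
cohort.

Signal drift multiplies responses by `(1 + drift)^(global injection
index)` (default 0.001/injection; 0.012 in the high-drift validation
scenario). Drift is applied to metabolite features but not to the internal
standard or creatinine — it models analyte-specific response decay relative
to the reference compounds, which is exactly the component that survives
normalization and must be handled by batch correction. Below-LOD censoring
removes, per feature, the values below the `lod_quantile` (default 0.05)
empirical quantile; the standard and creatinine are exempt because the
normalizations require them everywhere. Non-adherent participants (default
expected count 1 of 42) have their metabolite effects reversed while their
records keep the assigned arm's pattern, reproducing record–phenotype
discordance. Cross-fluid marker pairs (default 2, coupling 0.6) are built
by sharing standardized log deviations between a plasma planted feature and
a urine echo, so the pooled log-scale Pearson correlation recovers the
coupling parameter; the estimator operates on normalized responses, whose
residual reference-compound noise attenuates the estimate slightly
(measured means ≈ 0.53–0.57 for a coupling of 0.6).

### What the generator does not emulate

Correlated feature blocks (isotopologues, adducts, pathway co-regulation),
retention/migration-time drift, heteroscedastic technical noise,
matrix-specific interference, missingness mechanisms other than
LOD-truncation, and record-keeping error beyond the effect-reversal model.
Passing tests therefore demonstrate correctness of the algorithms under a
faithful but idealized noise model, not performance on any real cohort.

## Validation problem sizes

Oracle suites: 1000 random p-vectors (FDR), 100 random profile instances
(T²), 50 instances each for partial correlation and the F = t² identity,
all class-size pairs 2–6 with tie-forcing rounding (AUC). Null calibration:
200 generated cohorts, 24 plasma features each, n_perm = 200, with
censoring and non-adherence disabled so the check isolates the statistics'
calibration from imputation artefacts. Parameter recovery: 20 cohorts at
full default size. These sizes are the package's validation scale; all
suites are re-run from scratch by `scripts/acceptance.py`.

## Known limitations

* **Null specificity of the robust-call rule.** The moderated-T² and
  interaction tests are individually calibrated but strongly dependent
  (both test the arm contrast of the same profiles; measured joint null
  pass rate ≈ 0.018 at α = 0.05). With ~146 null features per cohort and
  nutrient deltas separated between arms by 3–4 SD — as the published
  record summaries imply — a null feature that accidentally correlates with
  arm usually also collects two nutrient hits, yielding on the order of 1–3
  false robust calls per cohort at default thresholds. This is a property
  of the decision rule at n = 24/18, not of any noise setting: all three
  models are scale-invariant t/F statistics. Tightening `n_nutrient_min` to
  3 or q-based model thresholds would trade sensitivity for specificity;
  both are exposed in `PipelineConfig`.
* The moderated-T² p-value is approximate for ν > 0 (slightly
  conservative); rankings, which the time-course analysis is primarily used
  for, do not depend on it.
* The mixed-model equivalence used for the interaction F is exact only for
  two timepoints; longer time series are out of scope.
* OPLS-DA autoscaling is performed once on the full matrix rather than
  refit per CV fold; observed and permuted statistics share the convention,
  so the permutation test remains valid.
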