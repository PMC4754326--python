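# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limits of what the test suite shows.

## Discriminant model

**Pre-processing.** Every feature block is mean-centered and scaled to
unit variance using the *sample* standard deviation (n−1 denominator, the
chemometrics convention). Scaling parameters are always estimated on the
training partition — inside each cross-validation fold, never on the full
data — and applied unchanged to held-out rows. A numerically constant
column raises an error naming the column rather than producing infinities.

**OPLS.** The two-class discriminant is a single-response OPLS model,
response coded CTL = 0 / AD = 1. For one response the algorithm is a
closed-form sequence (no iterative convergence): the predictive weight is
the normalized covariance direction `w ∝ Xᵀy`; each orthogonal component
removes, from the current deflated matrix, the part of the predictive
loading not collinear with `w`; the final regression `c = yᵀt/tᵀt` maps
the predictive score to the class scale, and predictions add back the
training prevalence `ȳ`. Consequences relied on elsewhere:

* a row at the training grand mean scores exactly `ȳ`;
* training predictions with `k` orthogonal components equal those of a
  (1+k)-component NIPALS PLS fit (tested against an independent oracle
  implementation to 1e−8 over random problems);
* predictive and orthogonal training scores are mutually orthogonal, and
  orthogonal scores are uncorrelated with the response (1e−10).

Scores are *not* clipped to [0, 1]; the 0/1 coding is what makes the
fixed 0.5 cut-off meaningful. The sign of `w` is oriented so the class
coded 1 has the higher mean score (pure convention; predictions are
invariant). Ties at exactly 0.5 classify as AD-like (`≥` rule; ties have
measure zero).

**Cross-validation.** Sevenfold, stratified by class with a recorded
seed; stratification falls back to a plain shuffled split (with a
warning) if a class has fewer members than folds. Q² = 1 − PRESS/SS with
deviations taken from the overall training mean. Everything data-driven —
scaling and, for the detrended strategy, the control-based detrender — is
refit inside each training fold, so Q² carries no leakage; a brute-force
per-fold refit loop reproduces it to 1e−10 in the tests. The number of
orthogonal components is the smallest whose Q² is within `tol = 0.01` of
the maximum over 0..5 (parsimony rule; both knobs configurable).
Complexity selection and final CV use the same fold assignment.

**Hierarchy.** Volumes (21) and thickness means (34) are modelled by
separate base OPLS models; the top model's inputs are the base models'
*cross-validated* scores during training — fitted scores would leak
training information upward and inflate the top-level Q² — plus the
scaled age column under the covariate strategy. At prediction time the
fully refit base models supply ordinary predicted scores. The top model
reuses the same folds as the bases. With covariate correction the top
model has three columns; its orthogonal components (selected by the same
Q² rule, typically one) are what actually remove the age-related
variation, since age itself has essentially no covariance with diagnosis
when the group age distributions match.

**Age detrending.** Per feature, ordinary least squares of the measure on
age, controls only — Gaussian OLS with identity link, because the aging
literature this correction leans on models healthy decline as linear
drift. The corrected value `x' = x − β̂₁(age − age_ref)` is anchored at
the control mean age so features keep their natural units and a zero
slope is the exact identity (rather than returning raw residuals).
Correction uses control-estimated slopes for all diagnostic groups: age
effects estimated in patients would absorb disease progression too. In
cross-validated fits the detrender sees only the training fold's
controls. Detrending is idempotent to numerical precision, and
residual feature–age correlation in the sample the fit was made on is
zero by OLS orthogonality.

**Univariate comparisons.** Correct vs incorrect subjects are compared
with the pooled-variance (Student) independent-samples t test for
continuous variables — Welch available via `equal_var=False` — and
Pearson χ² *without* continuity correction for 2×2 tables (the
uncorrected form is the one whose p-values match classical reporting
practice for tables of this size; Yates is visibly more conservative).
Significance is flagged at 0.05 without multiplicity adjustment, and
every rendered table carries a note saying so. Subjects with an unknown
level (e.g. missing ApoE) are dropped per variable, not at load.

**Reporting.** Percentages are rounded half-up to one decimal for
display; all comparisons in code and tests use the unrounded values, and
reported rates always reconcile exactly with their confusion counts.

## Synthetic cohort generator

The generator produces the study conditions for every test: 340 CTL, 360
stable-MCI, 85 progressive-MCI (progressed by month 12), 297 AD; group
age distributions ≈ 75 ± 5.7/6.9/6.5/7.0 years truncated to [55, 95];
sex, ApoE-e4 carrier, ADNI/AddNeuroMed cohort membership, education,
MMSE and CDR drawn per group from realistic marginals.

Feature `j` of a subject at age `a` is

```
baseline_j + slope_j (a − 75) + φ · d_j σ_j + σ_j (L_j f + u_j e)
```

* **Baselines and scales** are plausible FreeSurfer-style values
  (thickness 1.6–3.7 mm, volumes from ~50 mm³ vessel to ~52 cm³
  cerebellar cortex).
* **Disease effects** `d_j` are in residual-SD units: −1.5 for
  medial-temporal measures (hippocampus, amygdala, entorhinal,
  parahippocampal), −1.0 across the rest of the temporal lobe, −0.3
  elsewhere in tissue, +0.5 for ventricular/CSF spaces and +0.3 for
  slowly growing fluid/lesion measures — so variable importance
  concentrates in the medial temporal lobe, and a scaled-down analogue of
  the published accuracy regime (high-80s AD/CTL, mid-60s MCI) emerges.
* **Severity** `φ` is 0 for CTL and 1 for AD. Each MCI subject carries an
  individual latent severity: progressive MCI ~ TruncNormal(0.70, 0.13);
  stable MCI is a two-component mixture reflecting the clinical
  heterogeneity of the group — an eventually-converting (prodromal)
  fraction at the progressive-MCI level 0.70 and a never-converting
  component whose mean is solved so the stable-MCI group mean stays at
  the configured 0.30. Conversions at months 18/24/36 are assigned in
  decreasing severity order, at cumulative rates 0.11/0.25/0.34 of the
  stable group (follow-up past month 12 exists only in the ADNI
  sub-cohort; other subjects are "unknown" there). Progression therefore
  tracks latent severity, which is what makes longer follow-up improve
  prediction.
* **Residual correlation** uses two shared factors — a global
  atrophy/aging factor (loading 0.60 on every measure, signed by disease
  direction) and an AD-pattern factor (0.55 medial-temporal, 0.44
  temporal, 0.26 ventricular, 0.14 elsewhere) — plus unique noise filling
  the variance to 1. Fifty-five independent measures would make the
  classification problem unrealistically easy; the factor structure puts
  the achievable separation in the published range.
* **Age slopes** are the sum of a nonspecific background drift
  (median ≈ 0.065 SD/year, matching typical elderly-cohort feature–age
  correlations ≈ 0.35) and an AD-pattern-aligned component,
  `aging_similarity = 0.03` of the full disease pattern per year. The
  aligned part is the scientific crux: normal aging preferentially
  affects the same medial-temporal structures as the disease, which is
  exactly why old controls get misclassified as patients — a purely
  factor-collinear drift would be whitened away by the discriminant and
  produce no age-dependent misclassification at all.

`confounded_scenario(config, shift)` additionally lowers the AD group's
mean age, producing a *group-level* age–diagnosis confound. The
qualitative replication suite runs on the unshifted cohort: the reference
cohorts' group ages were nearly equal, and a group-level shift changes
the phenomenon (the covariate model then exploits age as a spurious
predictor, and between-group comparisons of misclassified subjects are
confounded by construction).

All calibration constants above were fixed once, from the design
considerations stated, before the replication tests were frozen.

### What the generator does not emulate

Scanner/site effects, longitudinal trajectories, left/right asymmetry,
non-linear aging, heavy-tailed measurement error, and any coupling of
MMSE, sex or ApoE to the imaging features (MMSE is simulated from group
marginals only). Passing tests therefore demonstrate the *machinery* —
correct OPLS algebra, leakage-free validation, effective age correction
under linear drift — not performance on real cohort data, where
correlation structure is richer and the linearity assumption only
approximate.

## Numerical choices and degenerate inputs

* Constant feature columns → explicit degenerate-feature error at
  scaling (relative threshold 1e−10 of the column mean, since rounding
  can leave a constant column with a tiny nonzero SD).
* Requested orthogonal components beyond the data's rank → rank error;
  complexity search stops there.
* Zero age variance or < 3 controls → detrend refuses to fit.
* Pearson correlations of numerically constant columns are reported as
  undefined (NaN) rather than noise ratios.
* Fold assignment, simulation and every stochastic step derive from one
  top-level seed through named SHA-256 substreams (all below 2³¹), so a
  single integer reproduces a full report byte-identically.

## Test-suite operationalizations

Two spec-level properties needed statistical care:

* *Slope recovery* at n = 1000 controls is judged jointly, not
  per-feature: the 55 slope errors share the factor-driven sampling
  noise, so "every feature within 3 SE" fails occasionally for a correct
  implementation. The suite whitens the error vector by its exact
  sampling covariance (known from the generator) and checks the χ²₅₅
  statistic against the 0.999 quantile, plus the median per-feature
  |error|/SE < 3.
* *Prediction accuracy vs follow-up* is asserted as median accuracy
  (20 replicates) non-decreasing month over month and strictly higher at
  month 36 than at month 12, for the detrended model.

## Known limitations

* The covariate strategy relies on the top model selecting at least one
  orthogonal component; with `tol` set very large it degenerates to the
  uncorrected model.
* Detrending can overcorrect old patients if their true age slope is
  shallower than the controls' (the generator gives all groups the same
  slopes, so this shows up only with real data).
* Single-level CV: the same folds select complexity and report Q², so
  Q² is mildly optimistic as an out-of-sample estimate; the published
  workflow this mirrors did the same.
* No missing-data machinery beyond rejection at load.
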