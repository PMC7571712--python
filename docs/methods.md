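# Methods

`npxpanel` implements the statistical workflow of a plasma-protein
biomarker discovery study in ovarian tumor diagnostics: given a cohort of
women with an adnexal mass, assayed on multiplex proximity-extension
panels (Olink NPX units, log2 scale, relative within protein), find
proteins and protein panels that discriminate benign tumors from
epithelial ovarian cancer (EOC), with and without borderline tumors on
the case side, and quantify what they add to the established serum
markers HE4 (gene `WFDC2`) and CA125 (`MUC-16`).

## Data model and contrasts

A cohort is a samples x proteins NPX matrix plus per-sample metadata:
tumor category (`benign`, `borderline`, `eoc_I` = FIGO stage I EOC,
`eoc_II_IV` = advanced EOC), histology, age in years (may be missing,
never imputed), and an assay QC-pass flag. Samples failing the vendor's
internal QC are excluded whole-sample before any analysis. Two binary
contrasts are built from the categories: benign vs cancer (borderline
samples dropped) and benign vs borderline+cancer.

## Stage 1 — differential expression

Each protein is tested with a two-sample t-test on the NPX scale.
"Student" (pooled variance) is the default variant; Welch is available as
a sensitivity flag because per-group SDs are visibly heterogeneous for
several proteins. P-values are adjusted across the full panel with
Benjamini–Hochberg (the standard step-up FDR procedure; implemented via
`statsmodels.multipletests`, property-tested against the brute-force
step-up formula). Two thresholds are exposed: a conservative significance
call at adjusted p < 0.001 and a reporting cut at adjusted p < 0.05.
Ranks order by adjusted p with ties broken by raw p, then protein name.

## Stage 2 — univariate ROC ranking

The empirical AUC is the Mann–Whitney estimator (ties count one half).
Because a marker that runs *lower* in cases discriminates exactly as well
as one that runs higher, the univariate ranking reports the
orientation-corrected AUC `max(a, 1-a)` with the flip recorded; ITGAV and
DNER are the motivating cases. Model-based AUCs (Stage 3 onward) always
score by predicted probability and are never flipped. Confidence
intervals are stratified percentile bootstrap (cases and controls
resampled separately; B = 2000 by default; seeded). Operating points use
achievable empirical thresholds only — a sample is called positive when
its score is >= the threshold, and no ROC interpolation is performed —
so every reported sensitivity/specificity pair is attainable on the data.
Three criteria are provided: maximum sensitivity subject to specificity
>= 0.95, the symmetric specificity at sensitivity >= 0.95, and the
Youden point (max J = sens + spec - 1, ties broken toward higher
specificity).

## Stage 3 — forced-core models and add-one scans

The reference model is an ordinary maximum-likelihood logistic regression
on HE4 + CA125 + age (age in years; AUC is invariant to predictor
scaling). Samples with missing age are dropped listwise for models that
contain age, matching the cohort's single missing-age patient. Each
candidate marker with univariate AUC > 0.7 is added in turn; the
augmented model's AUC is compared with the reference's using DeLong's
placement-value estimator of the variance of the paired AUC difference
(two-sided normal test, significant at p < 0.05). Both models are always
evaluated on the identical sample set. Reported AUCs are apparent
(in-sample), the convention for single-cohort discovery studies; a
stratified k-fold cross-validated AUC is available (`cross_validated_auc`)
for honest out-of-sample assessment — under permuted labels the apparent
AUC of the 3-predictor reference sits near 0.58 while the CV AUC is
centered on 0.5, which is why the null-calibration tests use the latter.
Perfect separation is flagged rather than penalized: downstream use is
rank-based, and coefficient blow-up does not change the score ordering.

## Stage 4 — stability selection and nested panels

The multi-marker selection procedure, per round:

1. stratified 50/50 split of the contrast samples;
2. on the training half, tune the lasso shrinkage λ by stratified k-fold
   cross-validation (k = 10) of the binomial deviance over a 30-point
   geometric λ path spanning two decades below the training λ_max,
   taking the deviance minimizer (a 1-SE rule is available);
3. apply that λ unchanged to the held-out half: an L1-penalized logistic
   fit with HE4, CA125 and age forced in unpenalized performs the
   variable selection; record the selected pool variables and their
   absolute standardized coefficients.

Ten such rounds are aggregated into a ranking (selection count
descending, then coefficient-magnitude sum descending, then name); the
lowest-ranked variable is eliminated and the whole loop repeats until the
pool reaches `stop_size` (default 2). The last `depth` (default 3) nested
pools are refit as ordinary logistic models on the full contrast and each
is DeLong-compared to the forced-core reference; the "final" panel is the
highest-AUC row whose comparison clears p < 0.05. The candidate pool
defaults to every assayed protein except the forced core — deliberately
wider than the AUC > 0.7 list, since useful panel members need not be
strong univariate markers.

The penalized solver is written in-package (numba-compiled IRLS +
cyclic coordinate descent with soft-thresholding, warm starts along the
path, active-set sweeps) because per-feature penalty factors — forced
variables carry factor 0 — are not available in scikit-learn. Its
coefficient paths were cross-checked against R `glmnet(penalty.factor=)`
during development. CV fold fits run at a coarser convergence tolerance
(max 5 IRLS iterations, tol 1e-3) than the selection fit (tol 1e-7); the
chosen λ was verified identical to tight-tolerance CV on 25 seeds.
Degenerate folds (a single-class fold) are refolded with a new seed a
bounded number of times, then error. The entire procedure is a pure
function of (data, configuration, master seed): round, cycle, fold and
bootstrap seeds all derive from the master seed via `SeedSequence`.

## The synthetic cohort generator

No patient-level data are public for this kind of study; what is public
are per-protein per-group NPX means/SDs (78 proteins for benign vs
cancer, 57 for the combined contrast), the cohort composition (30
benign / 28 borderline / 25 early / 97 advanced enrolled; 8 assay-QC
failures — 2 borderline, 6 advanced — leaving 172), per-category age
mean/range, and histology counts. The generator emulates exactly that:

* NPX values are Gaussian per protein per group on the log2 scale — the
  minimal model consistent with a printed mean/SD pair. Group membership
  follows the contrast parameterization; the panel is padded to 177
  proteins with null ("noise") markers, standing in for the
  assayed-but-non-significant remainder.
* An optional exchangeable correlation ρ (single shared latent factor)
  is the only dependence knob: the published tables carry no covariance
  information, and one knob suffices to exercise the multivariate stages.
  The default is ρ = 0, which makes simulated markers *independent* —
  noticeably more optimistic than real panels (e.g., the simulated
  HE4+CA125 reference model reaches apparent AUC ≈ 0.95 vs the reported
  0.838, because the real markers are correlated). Passing tests
  therefore validate the machinery and its calibration, not the clinical
  effect sizes.
* Ages are truncated normal per category, matching the printed mean,
  truncated to the printed range, SD set to range/4 (only mean and range
  are published). One benign sample has a missing age by default.
* Planted-marker cohorts (`simulate_planted_cohort`) carry `n_planted`
  markers shifted by a chosen standardized effect and `n_noise` null
  markers, with the HE4/CA125 columns either informative (drawn from the
  published parameters — used when a realistic reference model is the
  point, e.g. incremental-value power studies) or null (used for
  support-recovery studies, where the planted markers should be the only
  signal). The closed-form binormal AUC
  Φ((μ₁−μ₀)/√(σ₀²+σ₁²)) is the oracle against which all empirical AUC
  machinery is verified.

The generator does not model plate effects, limit-of-detection
censoring, duplicate-run noise, or non-Gaussian tails.

## Numerical choices and degenerate inputs

* Logistic fits standardize predictors internally and map coefficients
  back, making fits affine-invariant to ~1e-6; constant predictors are
  dropped with a warning.
* t-test with zero variance in both groups and equal means returns p = 1
  by convention; DeLong with zero variance and equal AUCs likewise.
* All-tied scores give AUC 0.5 and a degenerate operating point
  (sensitivity 0 at specificity 1 for the constrained criterion).
* λ values above the test half's λ_max legitimately select nothing; such
  rounds contribute zero counts to the ranking.
* Candidate-pool ties after zero selections rank alphabetically.

## Problem sizes used in the test suite

Simulation-based checks run at the cohort's own scale (30 controls vs
116 or 142 cases) with 50–500 replicates per experiment, chosen so the
whole suite completes on a single CPU in well under half an hour while
keeping Monte-Carlo error small relative to every asserted tolerance.
The calibration experiments (support recovery at planted effect 1.0,
end-to-end incremental power at effect 0.8, null-cohort false-positive
rates) use 20-marker candidate pools, R = 10 rounds and k = 10 folds —
the procedure's own defaults.

## Known limitations

* Independence between markers is the default simulation regime; real
  NPX panels are strongly correlated, and apparent AUCs simulated under
  independence overstate multivariate performance.
* Reported model AUCs are apparent; the optional CV AUC quantifies (and
  on null data removes) the optimism, but no bias-corrected bootstrap of
  the full selection path is provided.
* The elimination loop refits CV per cycle, so its cost grows
  quadratically in the initial pool size; the full-panel default
  (~175 markers) is minutes of CPU, not seconds.
* Under repeated splits of one fixed cohort, a null marker whose
  *realized* correlation with the outcome is large will be selected in
  many rounds — within-cohort selection frequencies are exchangeable
  across noise markers only on average over cohorts.
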