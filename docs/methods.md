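# Methods

`voc-ptb` re-implements, as a tested pipeline, a pattern-recognition
analysis of GC-IMS (gas chromatography–ion mobility spectrometry)
volatile-organic-compound profiles from vaginal swabs, used to predict
bacterial vaginosis (BV) and spontaneous preterm birth in a high-risk
antenatal population. This note documents the model, its parameters,
the synthetic-data generator, numerical conventions, and known limits.

## The analysis

Each swab yields a dense 2D intensity matrix over GC retention time
(seconds, rows) and IMS drift time (milliseconds, columns). The raw
matrix is large but information-sparse: analyte "circles" cluster in a
central region, a constant reactant-ion (RIP) column runs down the
drift axis, and the rest is detector background.

Dimensionality reduction has two steps, identical for every sample:

1. **Crop** to a rectangular window covering the informative region.
   The window is chosen *once* over many samples (originally by manual
   inspection; here `suggest_crop_window` offers a deterministic
   stand-in — greedy edge-trimming of the pooled above-threshold mass
   until a coverage fraction would be lost, default 0.99) and then
   frozen in the run configuration.
2. **Threshold** each cell: values strictly below the cutoff become 0;
   values equal to the cutoff survive (the tie direction is our
   convention, stated because the procedure's description does not fix
   it). Cells are zeroed, never deleted, so all samples share one
   rectangular feature space — required by the per-fold selection
   below. Features that end up zero in every sample are retained and
   handled by the selection's constant-feature policy (p = 1).

Cropped, thresholded matrices are flattened row-major into a samples ×
features table.

**Classification** uses class-balanced, stratified tenfold
cross-validation. Balancing subsamples the majority class uniformly at
random to the minority count, once per analysis (before fold
assignment); balancing per fold would be an alternative reading and is
noted as such. Within each fold, the training 90% alone ranks every
feature by a two-sided Mann–Whitney rank-sum p-value and the 100
smallest-p features go to the classifier (ties in p broken by larger
absolute rank-biserial correlation, then lower feature index). Two
classifiers are fitted per fold: a 1000-tree random forest with
sqrt-feature subsampling, and a Gaussian-process classifier with an
RBF kernel (length-scale initialised at 1 on standardised features and
optimised by marginal likelihood). Out-of-fold probabilities are pooled
over the ten folds, giving one test probability per sample.

Selecting features inside the fold is essential: selection on the full
data before splitting lets test labels steer the ranking.
`run_cv_leaky` implements that broken variant deliberately; on
label-free data with 2,500 features and 60 samples it inflates mean
AUC to ≈ 0.95 while the correct in-fold pipeline stays at chance
(`analysis/04_pipeline_validity.py` reproduces this).

**Evaluation.** AUC is the Mann–Whitney concordance probability,
(concordant + ½ tied) / (n₊ n₋); its ROC trapezoid equals it
identically and the tests assert agreement to 1e−12. The AUC 95% CI is
DeLong's placement-value estimator (no installed package exposes it,
so it is implemented here and cross-checked against a stratified
bootstrap, which remains available behind `auc_ci_bootstrap`). The
operating threshold maximises Youden's J over observed cut-points,
ties resolved toward higher specificity; a fixed 0.5 cutoff is a
config alternative, and both the threshold and the full confusion
counts are reported so the choice is transparent. Sensitivity and
specificity carry Clopper–Pearson exact 95% CIs (group sizes are
modest); PPV/NPV are reported as points. The "between groups" p-value
is a two-sided Mann–Whitney test comparing out-of-fold probabilities
of the two outcome groups — our reading of that summary statistic,
stated because the quantity is not otherwise specified.

## Cohort model

Gestational ages are integer days, displayed as "weeks + days".
Delivery categories partition days: < 24+0 midtrimester miscarriage
(boundary inferred from the risk-factor definition "midtrimester loss
< 24 wk"), 24+0–27+6 extreme preterm, 28+0–31+6 very preterm,
32+0–36+6 late preterm, ≥ 37+0 term; preterm = any non-term category.
Analysis sets follow the study design: BV labels a woman positive if
any swab in pregnancy tested positive; preterm analyses exclude
iatrogenic deliveries and unknown outcomes, and each patient
contributes one swab (earliest, or closest to delivery — the latter is
simply the latest swab, since delivery date is fixed per patient).

Group comparisons are normality-gated: Shapiro–Wilk at α = 0.05 must
pass in *both* groups for the pooled two-sample t-test (means ± SD
reported), otherwise Mann–Whitney with medians (IQR). Categorical
variables use chi-square without continuity correction, warning when
any expected count is below 5. Quartiles use the linear-interpolation
(type-7) convention; this is config-visible since IQR endpoints shift
across conventions. Whether the original tabulated comparisons used a
pooled or Welch t-test is not recoverable, so the t-branch is pooled
by declaration.

**A note on the published cohort counts.** The source cohort's
tabulated counts are internally inconsistent: 39/196 preterm overall,
but the BV-stratified split is 13/22 + 25/174 = 38, and two
delivery-category rows do not sum across columns. No patient-level
cohort can reproduce all five headline rates (12.0%, 19.9%, 59.1%,
14.4%, 9.2%) simultaneously. `CohortSummary.from_counts` therefore
computes each rate from its own published (count, denominator) pair —
which reproduces all five exactly, with percentages rounded half-up to
one decimal — while `summarize_cohort(patients)` computes the same
record self-consistently from patient-level data.

## Synthetic data

The generator targets statistical, not chemical, realism.

A spectrum is: positive detector baseline (default 2.0 intensity
units — raw instrument matrices are dense, every cell positive) with
Gaussian noise (sd 1.0), plus a constant RIP column (intensity 400 at
drift index 30), plus a fixed template of 2D Gaussian peaks (default
20 peaks placed uniformly in the central region, amplitudes
log-uniform in 30–300, σ_retention = 4 and σ_drift = 2.5 grid units),
each peak's amplitude jittered log-normally per sample (σ = 0.35). The
default grid is 300 × 200 — a desk-scale stand-in for the instrument's
millions of cells that preserves the sparsity structure the reduction
steps rely on. The default background threshold of 5.0 sits three
noise-sd above the baseline. A binary class effect multiplies the
amplitudes of designated peaks (default: ten peaks) — the simplest
mechanism the cell-intensity pipeline can detect; peak-position shifts
are a documented extension point, not implemented.

The cohort generator draws, per patient: BV ~ Bernoulli(0.12); outcome
iatrogenic (0.05), unknown (0.04) or spontaneous; preterm with
P(preterm | BV+) = 0.59 and P(preterm | BV−) implied by the 0.20
marginal (≈ 0.147, validated to be a probability at construction);
delivery gestation from the clinical-category mixture with weights
2 : 6 : 10 : 21 (midtrimester : extreme : very : late) for preterm and
a discretised normal centred at 39+3 (sd 9 days, truncated at 37+0)
for term; 2–3 swabs at distinct gestations uniform in weeks 10–29
(capped a week before delivery), sorted. By default the VOC effect is
applied to BV-positive patients' spectra, so preterm prediction works
only indirectly through the BV–preterm enrichment — mirroring the
biological reading that swab VOCs reflect the vaginal microbiome. The
effect can instead be keyed to preterm status or both. An optional
per-patient log-normal amplitude random effect (default off) stands in
for the unknown within-patient correlation of serial swabs.

All randomness flows from one seed through named crc32-keyed
`SeedSequence` sub-streams (per patient, per spectrum, per fold), so
regeneration is byte-stable and partial regeneration is possible.

**What passing tests show — and don't.** The synthetic spectra share
the real data's geometry (dense positive background, RIP, Gaussian
blobs, shared peak template) and the cohort shares its headline rates,
but peaks do not drift in position between runs, intensities have no
humidity or batch structure, and the class effect is a clean
multiplicative shift. Pipeline results on synthetic data validate the
*machinery* (no leakage, signal recovered when present, determinism);
they say nothing about how much VOC signal real swabs carry, and the
published headline AUCs are not reproducible without the original raw
spectra, which are not packaged.

## Numerical choices

* Rank-sum p-values: exact permutation enumeration (conditioning on
  the observed, possibly tied values) when both groups have ≤ 8
  samples; tie-corrected normal approximation (scipy, with continuity
  correction) otherwise. Constant features get p = 1, effect 0.
* Gaussian-process probabilities come from the Laplace approximation
  and are conservative: even on perfectly separated clusters they
  saturate near 0.82 rather than approaching 1. Ranking-based outputs
  (AUC, group p) are unaffected; threshold-based rates use the
  Youden-optimal cut on the pooled probabilities, which adapts to the
  compressed scale.
* Problem sizes for the validity experiments: 100 balanced samples on
  300 × 200 grids (null and signal), 60 samples × 2,500 exponential
  features (leakage), 10/5/10 replicate seeds respectively — sizes at
  which each property is decidable in minutes on one core. Replicate
  seeds are paired across effect sizes in the monotonicity check so
  the comparison is within-seed. At these sizes the null AUC is
  noticeably dispersed: the per-replicate sd is ≈ 0.09 (above the
  0.066 a binomial-only calculation gives at 50 + 50), because pooled
  out-of-fold probabilities carry per-fold calibration shifts. The
  null-control checks therefore characterise the centre of that
  distribution, not a tight per-run guarantee.
* Crop suggestion: greedy edge-trimming is exactly the above-threshold
  bounding box at coverage 1.0 (minimal by construction, verified
  against exhaustive search); below 1.0 it is deterministic but not
  guaranteed minimal.
* Zero-denominator rates (e.g. NPV with no negative predictions) are
  reported as NaN with a warning, never an exception; CV requires at
  least `n_folds` samples per class and says so in its error.

## Limitations

* No peak detection, alignment, or RIP normalisation — cells are the
  features, as in the original procedure; instrument drift between
  batches would hit this pipeline hard.
* No nested CV or hyperparameter tuning: one tenfold pass per
  classifier, by design.
* Balancing discards majority-class data; PPV/NPV are therefore
  computed at an artificial 50% prevalence and do not transfer to
  clinic prevalence without recalibration.
* The proprietary native instrument format is out of scope; spectra
  enter through the package's documented text dialect.
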