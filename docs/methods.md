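# Methods

`habitatrad` implements a habitat-aware, multiscale radiomics workflow for
predicting axillary lymph node metastasis (ALNM) from single enhanced-phase
DCE-MRI volumes with tumor segmentation masks.  This note documents the
model and its assumptions, the tunable parameters, the synthetic data the
package is validated on, and the numerical choices made where the design was
genuinely open.

## Preprocessing

Volumes are resampled to a 1 mm isotropic grid (trilinear interpolation;
masks nearest-neighbour so labels stay binary).  The output dimension per
axis is `round_half_up(dim * spacing / target)`, minimum 1 — a convention
chosen to match common resampler defaults and to make the resampling
contract testable.  N4 bias-field correction is wrapped from SimpleITK (the
algorithm is prior art; the package asserts its contract — a smooth
multiplicative field is removed, coefficient of variation inside a
homogeneous region decreases, repeated application is near-idempotent —
rather than its internals).  Intensities are then z-scored **within the
tumor-plus-ring support**, not the whole grid: whole-grid statistics depend
on how much background a scan contains, which would make intensity features
incomparable across cases.  Normalization can be disabled.

Segmentation QC uses the Dice similarity coefficient between two readers'
masks; cases below 0.85 (configurable) are flagged for adjudication.  Both
masks empty is defined as DSC 1 (with a warning); masks must share the image
grid — no silent world-space resampling, so registration errors surface
instead of hiding.

## Peritumoral rings

Rings are non-overlapping shells at 1, 3 and 5 mm built by Euclidean
distance-transform thresholding (distance <= d voxels on the 1 mm grid)
with subtraction of the inner expansion: ring1 covers (0,1] mm, ring3
(1,3] mm, ring5 (3,5] mm.  The distance-transform ball was preferred over
iterated cross-shaped dilation because it matches the physical millimetre
semantics exactly and is testable against an exhaustive distance-transform
oracle.  A cumulative mode ((0,d] expansions) is available behind a flag.
An optional valid-tissue mask clips rings to breast parenchyma; a default
threshold-based body mask (intensity above a configured fraction of the
robust maximum, largest connected component) stands in for the manual
editing a radiologist would do, because manual edits are not reproducible.

## Habitat mapping

Each tumor is partitioned into ~100 spatially constrained superpixels by
3D SLIC (scikit-image), run on per-case z-scored intensities restricted to
the tumor mask, compactness 0.1.  Nineteen first-order statistics summarize
each superpixel: mean, median, minimum, maximum, range, variance, SD,
skewness, kurtosis, energy, RMS, 32-bin entropy and uniformity, the
10th/25th/75th/90th percentiles, and the mean and robust mean absolute
deviations.  Shape and texture classes are deliberately excluded at the
superpixel level: on segments of a few dozen voxels they are unstable.
Degenerate conventions: skewness/kurtosis of a constant segment are 0;
entropy of a single-bin histogram is 0.

Superpixel features pooled over the training cohort are standardized
(pooled z-score) and clustered with K-means (k-means++, 10 restarts, fixed
seed) for each K in 2..10; the K maximizing the Calinski-Harabasz index is
selected.  The winning centroids, scaling statistics and CH curve are
frozen into a template; any case is then mapped by nearest-centroid
assignment of its superpixels, so habitat definitions are identical across
training, validation and test cohorts.  Habitat labels H1..HK are ordered
by descending centroid mean intensity to be comparable across runs.

Two numerical details matter here:

* **Winsorization.** Standardized features are clipped at |z| = 3 before
  clustering and mapping.  Superpixels that straddle a zone or tumor
  boundary by a single voxel produce histogram statistics (skewness,
  uniformity) 10-20 SDs from the bulk; K-means happily isolates a handful
  of such outliers into a singleton cluster, which *raises* the CH score at
  K+1 and corrupts model selection.  The clip is stored in the template so
  mapping applies the identical transform.
* **Zero-variance features** are dropped from clustering with a warning and
  recorded in the template.

## Radiomic feature panels

The extractor follows the common IBSI formulations for shape (14
descriptors on the original geometry), first-order statistics (18), and the
GLCM (24), GLRLM (16), GLSZM (16) and NGTDM (5) texture families, all
implemented in-package on top of numpy/scipy/scikit-image.  Texture
operates on a fixed-bin-width discretization (default 0.25 on the z-scored
intensity scale); directional families use the 13 unique 3D directions with
per-direction statistics averaged; GLSZM zones and NGTDM neighbourhoods use
26-connectivity.  Degenerate inputs yield defined values (constant region:
GLCM contrast 0, correlation 1 by convention) or missing values (texture on
a sub-2-voxel region), never crashes.

A panel is an explicit ordered enumeration of `{image}_{family}_{feature}`
names.  The packaged default panel has exactly 1,547 entries per region:
14 shape; 18 first-order on each of 17 derived images (original, 8
undecimated-Haar wavelet sub-bands, Laplacian-of-Gaussian at sigma 1-5 mm,
and sign-preserving square/square-root/logarithm transforms) = 306; the
four texture families (61) on each of the 17 derived images = 1,037; and a
reduced 19-statistic GLCM set at pixel distance 2 on the 10 least-smoothed
derived images (original, wavelets, 1 mm LoG) = 190.  The standard
transform/class products do not produce 1,547 uniquely, so the composition
is an explicit, versioned, overridable enumeration rather than implied
semantics; any other panel (e.g. the compact `small_panel` used for
desk-scale studies) can be supplied.  The wavelet filter bank is a
single-level undecimated Haar implemented as separable low/high-pass
correlations — same grid as the input, no padding constraints, and exactly
reproducible.

A habitat signature aggregates the per-region panels of the three habitats
(3 x 1,547 = 4,641 region-prefixed columns); whole-tumor and each ring
signature carry one panel each.  Missing cells (small or homogeneous
subregions) are imputed by K-nearest-neighbour column means (k = 5,
Euclidean distance on z-scored observed-feature overlap, backed by
scikit-learn's `KNNImputer` with the z-scoring inverted afterwards).

## Feature selection

Four stages with strictly nested survivors, all operating on features
z-scored with training-cohort statistics that are frozen for test-time use:

1. **Univariate filter**: two-sided Mann-Whitney U, keep p < 0.05.  A rank
   test was chosen because radiomic features are continuous and far from
   normal; no multiplicity correction is applied at this stage.
2. **Correlation pruning**: iteratively remove the feature with the most
   Pearson |r| > 0.9 partners until no pair exceeds the threshold.  Ties:
   larger mean absolute correlation, then lexicographic name — fully
   deterministic and order-independent.  Zero-variance features correlate
   with nothing and pass through.
3. **mRMR**: greedy forward selection of the mutual-information difference
   criterion (MID) after quartile discretization, keeping the top 32.
4. **LASSO logistic**: L1 path over 40 log-spaced penalties below the
   analytic lambda_max, stratified 10-fold CV (fold count scales down on
   small cohorts so each fold keeps both classes), penalty at minimum mean
   CV error (binomial deviance by default; squared-error available), refit
   on all training rows.  Nonzero coefficients define the Rad-score
   (linear predictor) used downstream.

## Models

* **Signature models** (whole-tumor, each ring, habitat): logistic
  regression, linear-kernel SVM (default) or ExtraTrees, fit on the final
  (LASSO-selected) features of the corresponding signature — falling back
  to the mRMR survivors when the selected penalty keeps nothing — and tuned
  by grid search over mean stratified 5-fold CV AUC; ties prefer the
  least-complex grid point.  SVM margins are mapped to probabilities by a
  Platt sigmoid fit on out-of-fold margins.
* **Clinical model**: univariate logistic screen per covariate (OR, 95% CI,
  p) with survivors entering a ridge logistic model.  The screen uses
  likelihood-ratio p-values: the Wald test collapses near separation
  (Hauck-Donner) and would silently discard the *strongest* covariates;
  under outright separation the p-value comes from the closed-form score
  test.  Encoding: BI-RADS ordinal integer, quadrant location one-hot
  (reference quadrant 1), laterality binary; missing numerics by median,
  categoricals by mode.
* **Combined model**: pure forward stepwise logistic regression over the
  habitat Rad-score, the 1 mm peritumoral Rad-score, and the screened
  clinical covariates; the candidate with the smallest likelihood-ratio
  p enters while p < 0.05, with no removal step.  A separation guard falls
  back to a weakly ridge-penalized fit and flags it.

Train/validation splitting is stratified (largest-remainder allocation per
class, default 7:3) and seed-reproducible.  No test-cohort information
enters any fitting path: scaling, calibration, thresholds and selection are
all frozen from training.

## Evaluation

* AUC with DeLong structural-components CI; paired model comparisons by the
  two-sided DeLong test (identical score vectors: p defined as 1).
* Threshold metrics (accuracy, sensitivity, specificity, PPV, NPV) at the
  training-cohort Youden-optimal threshold, frozen for other cohorts;
  ratios with empty denominators are reported as NaN, never 0.
* Hosmer-Lemeshow on predicted-probability deciles, chi-square with g-2 df
  (empty/tied bins merged with df adjusted).  The g-2 reference presumes
  probabilities fitted on the same data; with externally supplied true
  probabilities the statistic is approximately chi-square(g).
* Decision curves: net benefit NB(t) = TP/N - FP/N * t/(1-t) against
  treat-all/treat-none over t = 0.01..0.80 step 0.01.
* SHAP attributions: exact closed form for linear models (on the
  linear-predictor scale, additivity to 1e-6) and kernel-weighted coalition
  regression with the additivity constraint enforced exactly for tree
  models (probability scale, seeded, 2048 coalitions, tolerance 1e-2).
* Nomogram points table: the largest |coef x standardized range| maps to
  0-100 points, others proportionally; a total-points -> probability lookup
  is emitted and is consistent with `predict_prob` by construction.

## Synthetic cohorts

Real cohorts for this problem are private, so the package ships a
first-class generator.  Each phantom is a 64^3, 1 mm isotropic grid with an
ellipsoidal tumor (default semi-axes 12/10/9 mm, jittered per case)
composed of Z spatially contiguous zones (Voronoi-seeded by default;
nested shells available).  Zones are *texture-distinct*: they differ both
in mean enhancement and in heterogeneity (per-zone texture SD alternates
between 0.6x and 1.6x the nominal 0.3), with zone means spaced
`separation_sds` (default 3) pooled SDs apart.  The heterogeneity contrast
is deliberate: zones differing only in mean are collinear and equally
spaced in superpixel-feature space, which is the analytic worst case for
the Calinski-Harabasz criterion — merging two collinear clusters is
favoured at any separation — whereas real habitats (necrotic core,
proliferative rim) differ in more than brightness.  Heterogeneous zones get
proportionally finer texture grain (correlation length scaled by
sd_rel^(-2/3), clamped at the base length) so superpixel-level spread is
comparable across zones.  Texture is a Gaussian random field (smoothed
white noise, correlation length 1 mm); outside the tumor an exponentially
decaying enhancement gradient (per-case amplitude, 3 mm decay) models the
peritumoral microenvironment, plus global Gaussian noise (SD 0.05).
Per-case zone-mean offsets (SD 0.15, about half the pooled texture SD)
model inter-patient enhancement variability, so histogram modes do not sit
at identical positions in every case; the frozen-template habitat mapping
absorbs offsets of this size without mis-assigning zones.

Cohorts draw per-case geometry and gradient amplitude, build a clinical
table (age ~ N(48.4, 10.3); diameter from the actual phantom geometry so
image and table agree; quadrant location; laterality; BI-RADS 3-5), and
draw the binary outcome from a logistic model over the standardized
generative features with recorded weights — defaults 2.5 on zone-1 volume
fraction, 1.2 on gradient amplitude, 0.8 on diameter, 0.6 on BI-RADS,
intercept targeting 35% prevalence (resampled with a warning if the
realized prevalence leaves [0.1, 0.9]).  Everything is reproducible from
the seed.

What the phantoms do **not** emulate: MRI physics (coil profiles, k-space
artefacts, motion), multi-phase pharmacokinetics, non-ellipsoidal tumor
shapes, inter-scanner batch effects, and segmentation error.  Passing tests
on phantoms therefore demonstrate that the pipeline recovers planted
structure under its own assumptions — not clinical performance on real
cohorts, which the private source data makes unverifiable here.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run desk-scale studies chosen as
the smallest sizes at which the studied effects are stable: cluster-count
recovery pools ~100-superpixel features from 30 phantoms per cohort over 20
replicate cohorts; the end-to-end signal-ordering study uses 10 replicate
cohorts of 120 cases (70/30 split, a training cohort of realistic
single-centre size) at 64^3 with the compact panel; the
statistical-calibration studies use 1000 (DeLong) and 500 (Hosmer-Lemeshow)
replicates at n = 200 and n = 500.

## Known limitations

* On these phantoms the whole-tumor signature is a strong competitor to the
  habitat signature — often slightly stronger.  This is a property of the
  generative design, not a bug: the outcome is driven by zone composition,
  the gradient amplitude and diameter, and whole-tumor statistics read all
  three channels (mixture marginal moments encode composition; the
  tumor-plus-ring normalization support makes normalized tumor intensities
  reflect the gradient amplitude; shape encodes diameter), while the
  habitat signature carries the same information in three times as many
  candidate features.  The habitat-mapping machinery itself is accurate
  here (habitat masks agree with the true zones on >90% of voxels and the
  recovered habitat volume fractions correlate >0.9 with truth); a
  consistent habitat-over-whole-tumor advantage of the kind reported on
  real cohorts requires zone-specific signal (e.g. texture changes within
  one habitat) that marginal statistics dilute, which this generator's
  outcome model deliberately does not plant.
* The selection cascade and model tuning are not nested-CV-unbiased; the
  validation AUC of the selected model is mildly optimistic — an accepted
  trade-off of this cascade design.  Stability selection and bootstrapped LASSO are out of
  scope.
* The 1,547-name panel is a declared convention; other decompositions are
  equally consistent with the printed class totals.
* One enhanced phase per case is assumed; a second channel doubles columns
  when configured but no kinetic modelling is attempted.
* Gradient boosting is not part of the default model trio and sits behind
  no config flag in this release; the three supported algorithms are
  logistic regression, linear SVM and ExtraTrees.
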