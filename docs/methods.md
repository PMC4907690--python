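# Methods

This note documents the models implemented in `painsig`, the
assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the
numerical choices a careful user should know about.

## Signature scoring

A signature is a voxel weight map `w` over a brain mask; its response
to an activation image `x` is the dot product `s = Σ_v w_v x_v` over
the voxels the two masks share. The response deliberately excludes any
trained intercept: responses are compared within subject and
condition, where a constant cancels, and the field's convention
defines pattern expression as the weighted sum alone. Prediction of
ratings (`w·x + b`) does use the intercept. Whether an externally
supplied signature should carry its training intercept into scoring is
exposed through `VoxelPattern.intercept` / `predict`, default off.

Masks are never resampled implicitly. When a pattern and an image live
on the same voxel grid but different masks, scoring proceeds on the
intersection provided it covers at least 90% of the pattern's absolute
weight mass; below that a `CoverageError` reports the attained
coverage. Geometry mismatches are always errors.

All volumes are canonicalized to RAS orientation on read by axis
permutation/reversal only. The left-right flip used for the laterality
control is a pure reversal of the first canonical axis,
`(i, j, k) → (nx−1−i, j, k)`, applied identically to weights and mask;
it is an involution and adjoint to flipping the image.

## LASSO-PCR training and cross-validation

Training images are mean-centered (not voxel-standardized by default,
so weights stay in activation units and dot-product scoring is
meaningful), rotated into principal components via SVD, and intensity
ratings are regressed on the component scores with an L1 penalty. The
coefficients are back-projected, `w = V β`, and the intercept is
adjusted so `w·x + b` applies to raw images. By default every
component is retained (`n_components="full"`): the rotation is then
lossless and the L1 penalty does the selection. The penalty is chosen
by an inner 5-fold cross-validation over a 30-point log-spaced path
(seeded, hence deterministic); it may also be fixed. `λ = 0` with full
rank reduces exactly to minimum-norm least squares, which the tests
verify against a pseudo-inverse oracle. Voxels with zero variance in
the training set receive weight exactly 0.

Leave-one-subject-out cross-validation trains on N−1 subjects and
scores the held-out subject's images with that fold's pattern; a
subject's cross-validated responses are therefore a deterministic
function of the other subjects' data plus the config, which the suite
checks bit-for-bit. Cross-modality prediction reuses the fold
patterns: a subject's images of the *other* modality are also scored
only by the pattern trained without that subject.

The body-site classifier is a linear soft-margin SVM (C = 1 default,
solver tolerance 1e-8 so symmetry properties hold to high precision).
The positive class is the lexicographically larger label ("UL");
decision value 0 maps to the negative class.

ROI restriction subsets the mask and image columns; every trainer runs
unchanged on the restriction, which also implements the
exclusion-retraining control (train with a region removed).

## Statistical battery

- **Forced choice.** Per subject, condition A (designated
  higher-intensity) counts 1 if its response exceeds B's, 0.5 on a
  tie. The p-value is an exact two-sided binomial test against 0.5
  with ties excluded from the denominator. ROC points come from a
  threshold sweep; AUC is the pair-counting U statistic (ties 0.5),
  which the tests verify by exhaustive enumeration.
- **Paired/robust tests.** The paired t is a one-sample t on
  differences; zero variance raises rather than returning p = 0. The
  robust one-sample test is Huber IRLS (c = 1.345, ≤50 iterations,
  1e-8 tolerance) with the scale re-estimated each iteration as the
  normalized MAD of residuals — the convention statsmodels' RLM uses,
  against which the implementation is cross-checked. On clean data it
  reduces to the mean with the classical SE. The voxelwise group map
  uses the same vectorized IRLS.
- **Within-participant SEM.** Cousineau centering (subtract the
  subject mean, add the grand mean) with the Morey factor
  `sqrt(C/(C−1))`.
- **FDR.** Benjamini–Hochberg step-up; the reported threshold is the
  largest rejected p.
- **Bootstrap thresholding.** B resamples of subjects with
  replacement (a drawn subject contributes all images, once per
  draw); the trainer is refit per resample and voxelwise
  z = mean/SD of the weight distribution is referred to a two-tailed
  normal with BH-FDR at q. The pipeline fixes the lasso penalty at the
  value selected once on the full training set before resampling:
  re-selecting it per resample adds a multiplicative jitter to whole
  maps that inflates the weight SD and conflates penalty-selection
  variability with weight uncertainty (and holding hyperparameters
  fixed during bootstrap is standard in this method family). Voxels
  with zero bootstrap SD are excluded from testing and flagged. The
  desk-scale default is B = 200; the study-scale value (5000) is a
  config choice.
- **Conjunction.** Logical AND of two significance masks (each from
  the robust group map + FDR, q = 0.01 by convention for this use);
  an empty conjunction warns rather than errs.

## First-level models

The canonical HRF is the conventional double gamma (response delay
6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 6, 32 s
support), peak-normalized to 1; its mode on a dense grid is 5.0 s.
Regressors are boxcars convolved with this kernel on a 16× oversampled
grid; the discrete convolution is scaled by the fine-grid step so
regressor amplitude approximates the continuous convolution and does
not depend on the oversampling factor. GLM and beta-series estimators
are plain OLS — temporal autocorrelation is deliberately not modeled —
and rank deficiency is an error naming the collinear columns. Spike
detection computes per-volume slice-wise means and SDs, Mahalanobis
distance to the time-wise mean, and flags volumes above the
χ²(2·n_slices) quantile at Bonferroni-corrected alpha; when volumes
are fewer than twice the feature count the covariance uses
Ledoit-Wolf shrinkage (with a warning). Features are used raw, not
z-scored. Drift removal regresses out a discrete-cosine basis with
periods at or above the cutoff (224 s is the convention this models);
the residual is orthogonal to the removed span.

The smoothed FIR model estimates one beta per post-onset TR (25-point
window, 32.5 s at TR = 1.3 s) by penalized least squares with a
squared-second-difference penalty on adjacent timepoints and an
unpenalized intercept; λ = 0 is plain FIR OLS, and the default selects
λ by generalized cross-validation over a log grid on the data at hand,
since no canonical value exists. Applying a signature to each
timepoint map gives a signature time course; on synthetic data built
from one modality's pattern the other signature's course stays at
noise level throughout — the no-off-target-response check.

## Searchlight

Spheres collect in-mask voxels within a world-space (mm) radius of a
center — anisotropic voxels are handled through the affine, and ties
at exactly the radius are included; an interior 8 mm sphere on a 2 mm
grid has 257 members. Per sphere and per left-out run, a local pattern
(same LASSO-PCR by default, configurable) is trained on the remaining
runs of each modality; within-modality r correlates held-out
predictions with ratings across folds, and cross-modality r applies
one modality's local pattern to the other's held-out trials.
Zero-variance spheres yield NaN and are logged. Summaries report
top-fraction masks (ties at the cutoff are all included and counted)
and histogram tables. Full-brain center counts are a config choice;
desk-scale runs stride or subset the centers.

## Synthetic-data generator

Each subject-condition image is

    x = a_l·W_modality + site_effect·W_site + o_s·1 + ε ,

with level amplitudes `a_l ∈ {1,2,3}`, four latent patterns (somatic,
vicarious, upper limb, lower limb) built as Gaussian random fields
smoothed at 6 mm FWHM, mean-centered, Gram-Schmidt-orthogonalized, and
unit-normed (so all pairwise Pearson correlations are 0 to machine
precision), a subject-constant offset `o_s ~ N(0, 0.5)`, and noise ε
drawn white at sd 0.2 and then smoothed with the same kernel — the
kernel acts as a filter, so the realized per-voxel noise sd is smaller
than the nominal draw (≈0.10× at these settings). Ratings are
`clip(20·a_l + N(0, 5), 0, 100)`, i.e. linear in level on a 0–100
visual-analog-style scale. Defaults: 28 subjects, grid 20×24×20 at
2 mm with a one-voxel border excluded (7128 mask voxels), site effect
1.0. One seed drives named substreams (truth, data, ratings), so a
config reproduces its dataset byte for byte. A `signal_scale` factor
(default 1) scales the modality-pattern term; 0 gives null images for
calibration checks. Trial-level 4D runs are HRF-convolved boxcars
scaled by per-trial amplitudes on a latent pattern plus white noise,
built with the same design-matrix code as the estimators, so noiseless
recovery is exact.

What the generator does *not* emulate: temporally autocorrelated or
physiological fMRI noise, anatomical structure, susceptibility
artifacts, inter-subject spatial variability, or the cue-expectation
structure of real designs. Passing tests therefore demonstrate the
*estimators and inference machinery* behave as specified under the
assumed generative model, not that effect sizes on real data would
match.

## Validation conditions and a known stochastic limit

The standard validation conditions (28 subjects, orthogonal unit-norm
patterns, noise_sd 0.2) are deliberately high-SNR: within-modality
forced choice is then exactly 100%, cross-validated predictions
correlate with the generating levels above 0.9, trained patterns align
with the truth above cosine 0.8, and the site SVM exceeds 93%.

One quantity is intrinsically dispersed under these conditions: the
cross-modality forced-choice accuracy of ROI-restricted patterns.
Restricting two globally orthogonal smooth fields to any ~200-voxel
region leaves a residual correlation of order 1/√n_eff (≈0.1–0.2 at
6 mm smoothness), and because the per-subject response noise is small
at high SNR, this consistent leak drives each replicate's accuracy
toward 0 or 1 with a random sign. The mean over 20 replicate studies
× 2 directions is unbiased at 50% but retains a standard error of
roughly 6–8 percentage points; observed values across seed blocks
range from ≈38% to ≈56%. The corresponding test asserts the nominal
chance bound and can therefore fail for some seed blocks — this is a
property of the high-SNR study conditions, not of the estimator, and
is documented rather than hidden. The ROI itself is a fixed
200-voxel central block (the compact, anatomical-region-like choice);
a spatially distributed ROI shows the same mechanism.

## Reported problem sizes

Desk-scale defaults used throughout the tests and the acceptance
script: 336 images × 7128 voxels for full analyses, B = 200
bootstrap resamples, 20 replicate studies for the cross-modality mean,
strided centers on small grids for searchlight demonstrations. Larger,
study-scale settings (B = 5000, full-brain searchlight) are plain
config changes.
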