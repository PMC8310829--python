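# Methods

`ovarisk` implements a decision support system (DSS) that assigns an
adnexal (ovarian) mass a binary malignancy-risk class — *very low* vs
*medium-high* — from a single 2D transvaginal-ultrasound (TUS) frame plus
three pieces of clinical context: the mass echotexture class (solid /
cystic / mixed), the presence of a posterior acoustic shadow, and the
serum CA-125 level interpreted against a menopause-dependent cut-off.
This note records the model, the parameters that matter, the synthetic
phantom used for validation, and the numerical conventions.

## The decision model

The ultrasound-only risk comes from an ensemble of three binary
classifiers, one per echotexture class, fit on radiomic features of the
segmented mass. The final class applies three rules on top of it:

1. no acoustic shadow and CA-125 at or below threshold → the radiomic
   prediction stands;
2. acoustic shadow present and CA-125 at or below threshold → *very low*;
3. CA-125 above threshold, with or without shadow → *medium-high*.

The CA-125 cut-offs are 71 U/mL for postmenopausal women (twice the upper
normal limit of 35 U/mL) and 200 U/mL for premenopausal women, both
configurable. "Above" is a strict inequality: the phrase commonly used for
these cut-offs ("higher than") suggests strictness, the choice only
matters exactly at the boundary, and it is documented here because some
convention must be fixed. The radiomic model is always evaluated and
logged for audit, but on an override route it cannot change the outcome.
CA-125 dominates the shadow rule.

## Segmentation robustness by contour manipulation

The segmentation is manual. To keep the radiomics from depending on the
individual operator's tracing, the contour is randomly manipulated into
`n_variants` plausible alternatives: each variant displaces every vertex
radially from the contour centroid by a smooth random field, a sum of the
first `smoothness` Fourier harmonics in vertex angle with random
amplitudes and phases, rescaled so the peak displacement is at most
`amplitude_frac` of the contour's equivalent radius. Defaults:
`n_variants = 20`, `amplitude_frac = 0.05`, `smoothness = 6`. These
values are our choice — small, smooth deformations of the size one sees
between two careful operators tracing the same mass; 20 variants is
enough for stable intraclass-correlation estimates. The centroid-radial
parameterization (rather than per-vertex jitter) guarantees a smooth
simple closed output curve for star-shaped contours; at the default
amplitude every variant keeps a Jaccard overlap of at least 0.85 with the
original mask. Variants escaping the frame are clipped with a warning.

Rasterization uses the even-odd pixel-center rule with the half-open
boundary convention (an axis-aligned `[a, b)` box contains exactly
`(b-a)^2` pixel centers); the largest connected component is kept, and
masks below 50 pixels are rejected as too small for texture estimation.

## Radiomic features

All features are 2D, computed inside the mask, following the IBSI
definitions of the four families:

- **first order** (13): mean, variance, skewness, kurtosis, energy,
  entropy, 10th/90th percentiles, IQR, range, mean absolute deviation,
  RMS, uniformity;
- **shape** (9): area, perimeter, equivalent diameter, ellipse axes,
  eccentricity, circularity, solidity, maximum Feret diameter;
- **GLCM** (8 per distance, distances {1, 2, 4} px): contrast,
  dissimilarity, inverse difference, angular second moment, correlation,
  joint entropy, cluster shade, cluster prominence — symmetric matrices
  per angle (0°/45°/90°/135°), features averaged over angles;
- **GLRLM** (7) over the same four directions, averaged; **GLSZM** (5)
  with 8-connected zones.

Gray levels are discretized with a fixed bin number (default 64) over the
ROI min–max range: `level = 1 + floor(n_bins (I − min)/(max − min))`,
clamped at `n_bins`; a constant ROI maps to level 1. For mixed masses the
entire catalogue is additionally computed on the solid subregion
(Otsu-thresholded within the contour, prefix `solid_sub::`), since the
mural solid component carries most of the diagnostic texture. The
candidate catalogue is identical across mass types; panels diverge only
at stability selection.

Numerical conventions worth stating:

- the perimeter uses the Crofton estimator (4 directions). A raw
  iso-contour staircase overestimates smooth boundary length by ~6%,
  which would push a digital disk's circularity to ≈0.89; Crofton keeps
  it at ≈0.99, consistent with the analytic limit.
- solidity divides the pixel count by the geometric area of the convex
  hull of the pixel-corner cloud, so a square of pixels has solidity
  exactly 1 and the denominator is checkable against any independent
  convex-hull implementation.
- GLCM correlation of a single-level (degenerate) ROI is defined as 1;
  no feature is ever NaN or infinite.
- a distance at which no within-mask pixel pair exists is omitted with a
  warning rather than emitting arbitrary values.

## Stability selection

Features are kept only if stable across the contour variants, scored by
the one-way intraclass correlation ICC(1,1) with masses as subjects and
variants as interchangeable raters:

    ICC = (MS_between − MS_within) / (MS_between + (k − 1) MS_within)

clipped to [0, 1]; ragged designs use the harmonic-mean k; zero-variance
features are flagged degenerate and excluded. The selection threshold is
ICC ≥ 0.75, the conventional "good reliability" criterion in radiomics
robustness studies, configurable. Panels are selected per mass type on
training data only and frozen into the model file (descending ICC, name
as tie-break, so selection is order-invariant).

## Classifier ensemble

Per mass type: z-score standardization (fit on training data only),
then a linear SVM with C = 1 by default (logistic regression and random
forest are available). The continuous decision score is thresholded at
the operating point that maximizes sensitivity subject to a specificity
floor (default 0.75) — the clinical intent is to miss as few cancers as
possible while keeping false positives tolerable. Reported performance is
stratified k-fold cross-validation (default 10 folds, reduced when a
stratum is small) with the operating threshold re-chosen inside each
training fold, so test folds never leak into threshold selection; the
final model is refit on all training data. At inference the per-variant
feature vectors are aggregated by the median before scoring; the median
is what makes the prediction nearly invariant to the exact manual
tracing. Models serialize to JSON with exact float round-trip (linear
families store coefficients directly; the random forest stores a
base64-encoded estimator blob).

## The synthetic phantom

No patient images ship with the package, so every claim is exercised on
a statistical phantom designed to reproduce the structure the DSS
exploits, not the physics of B-mode imaging:

- background: a smooth tissue-intensity field (base 110, vertical
  gradient +25 over the frame, 8-bit scale) times unit-mean Rayleigh
  speckle smoothed by a Gaussian of σ = 0.8 px;
- the mass is a randomly tilted, randomly eccentric ellipse whose radial
  profile is roughened by Fourier harmonics 2–8. Peak relative roughness
  is drawn from U(0.01, 0.05) for benign and U(0.08, 0.15) for malignant
  masses — boundary irregularity is the morphological malignancy cue;
- interiors: cystic ≈ 32 (hypoechoic), solid ≈ 175 (hyperechoic); mixed
  masses are cystic with 1–3 solid mural nodules on the inner wall. A
  band-limited multiplicative heterogeneity field (contrast 0.06 benign,
  0.30 malignant) is the textural malignancy cue;
- a posterior acoustic shadow, when present, multiplies a slightly
  narrowing trapezoidal band below the mass by 0.35;
- CA-125 is log-normal with medians 25 U/mL (benign), 250 (malignant,
  premenopausal) and 150 (malignant, postmenopausal), σ_log = 1.0 / 0.9,
  so the class-conditional medians straddle the decision cut-offs the way
  the rules assume;
- cohort assignment: P(shadow) = 0.30 benign / 0.05 malignant,
  P(postmenopausal) = 0.60; frames are 128×128 px at 0.2 mm/px; the
  malignant count is exactly round(n · prevalence); one master seed
  derives per-case seeds, so cohorts re-generate byte-identically.

What the phantom does *not* emulate: point-spread-function blur and its
depth dependence, scatterer physics, acoustic artifacts other than the
shadow band, probe-dependent gain curves, neighboring anatomy, and the
real (much weaker, overlapping) feature distributions of clinical masses.
Passing the synthetic end-to-end checks therefore demonstrates that the
pipeline is correct and reproducible — that stable features are found,
the ensemble learns the constructed class structure, and the rules
integrate as specified — not that the classifier would reach the same
accuracy on patients. The benign/malignant contrast is deliberately
generous (cross-validated sensitivity and specificity on the default
cohort are well above the 85% the end-to-end check requires), because the
purpose is pipeline validation, not difficulty calibration.

Problem sizes used by the validation suite and the acceptance script —
our choice of a compact but non-trivial study: training cohort n = 300
(prevalence 0.5), held-out test n = 100, between-examiner reproducibility
on 200 phantoms segmented twice with independent perturbation draws,
texture-oracle equivalence on 100 random 6×6 ROIs, and Monte-Carlo
checks of the CA-125 model at n = 10⁴.

## Evaluation

Predictions are compared with the binary histology reference; *medium
high* paired with *malignant* is the positive outcome. Sensitivity,
specificity, accuracy, PPV and NPV are reported as ratios and
percentages (rounded half-up to one decimal) with exact Clopper–Pearson
95% confidence intervals from beta quantiles, with the closed-form
boundary cases low = (α/2)^(1/n) at x = n and high = 1 − (α/2)^(1/n) at
x = 0. The exact method is the only standard "binomial" interval whose
bounds match worked reference values such as a lower limit of 83.2% for
20/20; it is conservative (coverage ≥ 95%). A metric whose denominator
is zero is reported as undefined rather than fabricated.

## Known limitations

- The phantom's class separation is constructed; no claim about clinical
  accuracy transfers from it.
- Radial contour perturbation assumes star-shaped contours; extremely
  concave tracings could self-intersect at high amplitude (amplitude is
  capped at 0.15 for this reason).
- The feature catalogue covers the four standard 2D IBSI families;
  wavelet/filtered-image features and 3D features are out of scope, and
  AUC estimation is deliberately not provided (the DSS outputs a class,
  not a calibrated probability).
- Histological subtypes are not modeled; the label is strictly binary.
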