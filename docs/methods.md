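# Methods

## Synthetic speckle phantoms

Ultrasound B-mode texture is dominated by speckle, whose intensity
statistics are conventionally modelled with gamma-family distributions.
Each synthetic field is built as i.i.d. Gamma(k, 1) noise (shape k =
`skew_shape`), smoothed with a Gaussian kernel of standard deviation
`correlation_length_px`, standardised to zero mean / unit variance, and
mapped affinely to `mean_level + contrast_scale · z` before clipping to
[0, 255] and rounding to 8-bit. Consequences of this construction:

* skewness and kurtosis of the masked histogram decrease monotonically
  with k (and with the smoothing length, by central-limit mixing), so
  first-order separation between classes is directly controllable;
* the lag-1 autocorrelation increases monotonically with the smoothing
  length, giving second-order (co-occurrence/run-length) separation;
* `skew_shape → ∞` with `contrast_scale → 0` degenerates to a constant
  field at `mean_level`.

Lesion masks are star-shaped perturbed ellipses (radial Fourier modes
2–4, relative amplitude 0.15), which guarantees one connected blob, and
are kept at least 2 px off the image border so every matrix direction is
defined. All images of one lesion share one mask and one patient id;
fat/glandular samples use a large centred rectangle (the "maximal
continuous tissue area" a reader would trace) and their own patient
ids. A second reader is simulated by dilating or eroding the true mask
by one pixel (seeded coin flip), for ICC experiments.

Default cohort (the package's standard study conditions): 20 patients
per class, 2–16 images per lesion (uniform), 2 tissue images per
patient, 128×128 images, lesion radii 16–28 px. These sizes reproduce
the scale of a small ABUS reading study: lesion ROIs of ~1–3 k pixels,
tissue ROIs of ~10 k pixels, a few hundred images overall. Class
parameters (mean level, contrast, correlation length, gamma shape) are
chosen far apart so that the default cohort is a positive control;
`default_class_params(separation)` interpolates all classes toward a
common midpoint, and `null_pair_cohort_spec` makes two classes
identical for null calibration.

What the generator does **not** emulate: depth-dependent attenuation
and focusing, shadowing/enhancement artefacts, anatomical structure
(ducts, Cooper ligaments), inter-scanner variation, and correlated
noise between images of the same lesion beyond the shared mask.
Passing tests therefore demonstrate correctness and calibration of the
pipeline, not clinical performance on real ABUS data.

## Preprocessing

σ is the *sample* (n−1) standard deviation of the masked pixels; the
μ ± 3σ band is computed from the pre-clip moments and out-of-band
values are **clipped** to the nearer bound (not rescaled). Clipped
values are then binned into `Ng` equal-width, upper-half-open bins over
their own min–max range (min → level 1, max → level Ng). Ng defaults
to 64 — common radiomics practice for 8-bit inputs. A constant ROI is
rejected as degenerate (no 6σ band exists). Quantized levels are
invariant under positive affine transforms of the input, a direct
consequence of min–max binning.

## Texture engine

* **GLCM**: symmetric, four directions (0°, 45°, 90°, 135°); pair
  counts are *accumulated over directions into one matrix* and then
  normalized once (rather than averaging per-direction features — the
  two differ only through per-direction pair-count weighting; the
  accumulation convention is what the oracle tests pin down). Two
  distances (1 and 2 px) give the two co-occurrence feature blocks.
  Degenerate marginals (σᵢσⱼ = 0) make correlation undefined; it is
  reported as 0 with a `RuntimeWarning` so vectors stay finite.
* **GLRLM**: maximal equal-level runs along in-mask collinear segments;
  an out-of-mask pixel terminates a run. The direction-averaged block
  sums the four per-direction count matrices before computing features;
  run percentage is Nr/(n_directions·n_pixels) so it stays in (0, 1].
  The horizontal-only block repeats the eleven features on 0° runs,
  reproducing the duplicated run-length feature names found in
  published ABUS texture tables.
* **GLSZM**: 8-connected equal-level zones (Thibault's definition);
  zones partition the mask, so Σ size·count = n_pixels exactly. GLV and
  ZSV are variances of level and size under the zone-probability
  distribution.
* **First order**: entropy in bits from an equal-width histogram
  (default 64 bins over the clipped range); variance/skewness/kurtosis
  are population moments of the clipped values; kurtosis is excess
  (normal ⇒ 0).

Canonical order: 4 histogram + 4 GLCM@d1 + 4 GLCM@d2 + 11 GLRLM
(direction-averaged) + 11 GLRLM (horizontal) + 13 GLSZM = 47. Every
matrix builder and feature is tested against brute-force enumeration
(all pixel pairs, runs by scanning, zones by flood fill) on hundreds of
random small ROIs at 1e-10 relative tolerance.

## Classification pipeline

* Standardization (zero mean, unit variance) is fitted on training rows
  only; constant training columns pass through centred with scale 1 and
  are flagged.
* Balancing removes whole patients from the majority side of each
  binary task, choosing (seeded) among the patients whose removal
  shrinks the image-count gap the most, until no whole-patient removal
  improves it. No oversampling.
* Splitting moves whole patients into validation per class stratum
  until the validation image fraction is as close to the target (0.2)
  as whole patients allow; train and validation patient sets are
  disjoint by construction, and a leak-audit test verifies that
  corrupting validation rows leaves all training-side artifacts
  unchanged.
* Grid search: exhaustive over C ∈ {1, 10, 100, 1000} × γ ∈ {1e-5,
  1e-4, 1e-3} (logarithmic, endpoints as published for this workflow),
  scored by mean accuracy under patient-grouped stratified 5-fold CV;
  ties break toward the smallest C, then the smallest γ (the smoother
  model). "Validation accuracy" for model selection is read as mean CV
  accuracy on the training partition.
* RFECV: an RBF kernel exposes no per-feature weights, so the ranking
  estimator is a linear-kernel SVM (|w| importance), eliminating one
  feature per iteration; the subset size maximising CV accuracy wins,
  smaller sets win ties. The selected set is then re-standardized,
  re-tuned and refit with the RBF-SVM.
* Probability scores come from Platt (sigmoid) calibration of the SVM
  decision values on internal seeded stratified training folds; the
  hard label is score ≥ 0.5. Platt's smoothed targets make scores
  *approximately* (not exactly) antisymmetric under label flipping —
  the test tolerance reflects that.

## Evaluation statistics

* AUC is the Mann–Whitney statistic (ties ½), computed via midrank
  placement values; its variance is the DeLong estimator S₁₀/m + S₀₁/n,
  and the 95% CI is formed on the logit scale to stay inside [0, 1].
* Correlated-curve comparison uses the DeLong covariance of the two
  placement-value vectors and a two-sided normal test. Identical score
  vectors short-circuit to Δ = 0, p = 1; zero variance with a nonzero Δ
  raises a diagnostic error. A 500-replicate simulation in the test
  suite confirms the type-I error at α = 0.05 stays within [0.03, 0.08].
* ICC is ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — from the ANOVA mean squares, with the McGraw–Wong
  F-based CI (Satterthwaite df). Categories: ≤ 0.40 poor/fair,
  (0.40, 0.60] moderate, (0.60, 0.80] substantial, > 0.80 almost
  perfect. The implementation is cross-checked in tests against both a
  hand mean-squares formula and an independent library.
* The four-group per-feature ANOVA uses a fixed significance gate of
  p < 1e-4 (a Bonferroni-style screen for 47 simultaneous
  comparisons); degenerate inputs (no variance anywhere) map to
  F = 0, p = 1.
* Constant columns in the correlation matrix get zero off-diagonal
  entries and are flagged rather than producing NaNs.

## Determinism and problem sizes

A single experiment seed fans out to per-stage sub-seeds through a
`SeedSequence`-based counter scheme (`abustex.seeding.derive_seed`), so
identical config + seed gives byte-identical reports and any stage can
be rerun in isolation. Null-calibration experiments use a reduced
cohort (16 patients/class, 64×64 images, 3–6 images per lesion) —
chosen as the smallest scale at which patient-grouped 5-fold CV and the
0.2 validation split remain well defined while keeping repeated-seed
runs cheap; because a single null validation AUC at this scale has a
standard deviation near 0.1, calibration is asserted on the mean across
seeds rather than per seed.

## Known limitations

* The exact grouping conventions of the 47 features (distances,
  directions, Ng) vary across published texture toolkits; ours is a
  declared, internally consistent convention, not a certified IBSI
  correspondence.
* Wavelet/filtered features and 3D texture are out of scope.
* The reduced feature set on strongly separated synthetic data often
  collapses to very few features; realistic RFS sizes require realistic
  (weaker, correlated) class separation.
* DeLong comparisons assume paired scores on identical validation
  samples; the unpaired mode simply adds variances.
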