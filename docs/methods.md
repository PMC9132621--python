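# Methods

## Problem setting

The package classifies small grayscale images into two classes whose
difference is structural: one class dominated by oriented parallel
bands, the other by a compact dome-shaped blob with a bright midline
streak. This mirrors the sonographic signs used to sex a fetus on a
transverse ultrasound crop of the genital region (labial parallel lines
vs. phallus/scrotum dome). All computation is on `[0, 1]` float
intensities; inputs are standardised to 256 × 256 by bilinear resampling
(anti-aliasing on downscale only).

## Pyramidal fixed-size patch decomposition

Average pooling with non-overlapping blocks of side 2, 4, 8 and 16
produces levels of 256, 128, 64, 32 and 16 pixels (the original image is
level 0). Each pooled pixel is the arithmetic mean of its source block,
so pooling preserves the global mean exactly and nested pooling composes
(pooling by 2 twice equals pooling by 4). Every level is tiled into
16 × 16 patches, giving per-level counts (256, 64, 16, 4, 1), 341 in
total; the coarsest level is itself the last patch. Patch order is
frozen — levels in pyramid order, row-major within a level — because
selected feature indices are only meaningful under a fixed ordering.

## Descriptors

**LPQ (256 values).** A short-term Fourier transform with a uniform
3 × 3 window is evaluated at the four lowest non-zero frequencies
(1/3, 0), (0, 1/3), (1/3, 1/3), (1/3, −1/3) over the valid region only
(14 × 14 positions on a 16 × 16 patch; no padding, so border artefacts
cannot dominate a tiny patch). The eight real/imaginary channels are
decorrelated with the whitening transform implied by an exponential
pixel-correlation model (ρ = 0.9; SVD of the model covariance), their
signs form an 8-bit code, and the 256-bin code histogram is normalised
to sum 1. Coefficients that are zero in exact arithmetic (e.g. on
locally constant windows, where the filter sums vanish) are snapped to
zero before sign quantization, which makes the descriptor exactly
invariant to additive intensity shifts and makes a constant patch
deterministically produce a single spike at code 255. Window side,
ρ and histogram mode are exposed via `LPQParams`.

**HOG (36 values).** Gradients come from 3 × 3 Sobel kernels with
reflective borders; orientation is the unsigned gradient angle in
[0°, 180°). Magnitudes are split linearly between the two orientation
bins bracketing the angle (9 bins, centres 0°, 20°, …, 160°, wrapping
at 180°), accumulated over four 8 × 8 cells, concatenated into the
single 2 × 2-cell block and L2-Hys normalised (L2, clip at 0.2,
re-normalise; ε = 1e-12 in denominators so all-zero blocks stay zero).
This is the unique common HOG parameterisation that yields 36 values on
a 16 × 16 patch. The descriptor is shift-invariant and, after
normalisation, nearly invariant to positive intensity scaling.

Per patch, LPQ is concatenated before HOG (292 values); per image, the
341 patch vectors concatenate in patch order to 99,572 values. Column
provenance (patch index, pyramid level, descriptor family, within-family
index) is available as a table.

## Two-stage feature selection

**Chi-square filter.** Each feature is discretised into 10 equal-width
bins over its observed range (constant features score 0) and scored by
the Pearson statistic of the bin × class contingency table; the top 1000
features by descending score (ties: ascending index) pass to stage two.
Binning width and the 1000-feature cut are fixed configuration
constants, not tuned quantities.

**NCA weighting.** With features min-max scaled to [0, 1] per column,
NCA maximises the soft leave-one-out objective
Σᵢ pᵢ − λ Σᵣ wᵣ², where p_ij ∝ exp(−Σᵣ wᵣ² |x_ir − x_jr|) (p_ii = 0)
and pᵢ sums p_ij over same-class j. Optimisation is projected gradient
ascent from all-ones weights with step halving whenever the objective
would decrease, at most 200 iterations, relative tolerance 1e-6, and
λ defaulting to 1/n. The procedure is deterministic; non-convergence
returns the best iterate with a warning. Min-max scaling before
NCA/kNN is a documented assumption (the LPQ histogram and HOG value
ranges differ, and both NCA and Euclidean kNN are scale-sensitive).

**Prefix sweep.** Features are sorted by descending weight (ties:
ascending index) and every prefix size ℓ in [100, 1000] is scored by
pooled stratified 10-fold 1-NN (Euclidean, unweighted) cross-validated
misclassification; the smallest ℓ attaining the minimum wins. For the
default error function the sweep maintains the pairwise squared-distance
matrix incrementally as columns are appended, so the whole sweep costs
O(n²·d); a test asserts exact agreement with the generic per-ℓ kNN
evaluation. Non-default error functions (other k, metric or vote
weighting) use the generic path.

**Selection scope.** The default whole-data scope fits the selector
once on all data; any subsequent cross-validated estimate on the same
data is therefore optimistically biased (label information leaked
through selection). `fold_internal_cv_error` refits the entire selector
inside each outer fold and predicts held-out observations, which stays
at chance on label-independent features. A test demonstrates the
distinction on pure noise. Headline numbers from the default scope
should be read as in-sample selection optima, not generalisation
estimates.

## Classifiers and tuning

Reference hyperparameters per family: kNN k = 70, correlation distance,
squared-inverse (1/d²) vote weights; linear discriminant without
shrinkage (ridge fallback with a warning if the within-class covariance
is degenerate); Gaussian naive Bayes; Gaussian-kernel SVM with box
constraint 3 and kernel scale 5.6 (kernel scale s maps to
γ = 1/s² in exp(−γ‖x−z‖²)); decision tree with entropy splits and at
most 51 splits (52 leaves). Correlation-distance kNN is implemented as
Euclidean kNN on row-standardised vectors — the correlation distance
equals half the squared Euclidean distance between them, so neighbour
ranking is identical, vote weights are converted accordingly, and
zero-variance rows remain well-defined; a test cross-checks against
scipy's correlation distance. kNN's k is clamped to the training-fold
size when folds are small.

Tuning is Bayesian optimisation with a Gaussian-process surrogate
(Matérn-5/2 plus white noise) and expected-improvement acquisition over
family-specific spaces: kNN k ∈ [1, 100] and distance ∈ {euclidean,
correlation, cosine}; SVM log-box ∈ [1e-2, 1e3] and log-scale ∈
[1e-2, 1e2]; tree splits ∈ [2, 200]; LD shrinkage ∈ [0, 1]; NB variance
smoothing log ∈ [1e-12, 1e-6]. The reference spec is evaluated first,
so the incumbent can never be worse than it on the tuning folds; finite
spaces are enumerated as the candidate pool, so a budget covering the
space degenerates to exhaustive search. All CV evaluations inside one
tuning run share one seeded fold partition; final reported metrics use a
fresh partition (seed + 1) so headline numbers are not the tuning
incumbents themselves. Everything is deterministic given the seed.

## Metrics

Accuracy, precision, recall and F1 are computed from pooled CV confusion
counts and reported in percent; the positive class defaults to "female"
and is configurable (swapping it transposes fp↔fn, tp↔tn). Per-class
and macro-averaged variants are emitted alongside the positive-class
headline. Zero-denominator precision/recall fall back to 0 with a
warning. ROC curves sweep the unique continuous scores (tied scores
step simultaneously) and AUC is trapezoidal, equal to the normalised
Mann–Whitney U statistic.

## Synthetic data

The generator emulates what the pipeline needs from real data — two
classes separated by oriented-band versus blob structure under
multiplicative speckle — and nothing more. Background: a smoothed
Gaussian random field around intensity 0.35 with a mild depth
attenuation. Female-like images add 2–4 parallel curvilinear Gaussian
bands (random orientation, spacing 4.5–7 % of the image side, random
curvature); male-like images add an elliptical dome plus a near-vertical
echogenic streak. Structure amplitude is 0.45 × separability, so
separability 0 makes the classes exchangeable by construction. Images
are clipped, blurred (σ = 1 px) and multiplied by i.i.d. unit-mean
Gamma(looks) speckle, looks = 4 by default — the fully developed speckle
model at a realistic single-frame look count. The generator does not
model beamforming, attenuation shadows, probe geometry, anatomical
variability or operator effects; a pipeline that separates these
synthetic classes demonstrates that the descriptors and the selector
capture oriented-vs-blob contrast under speckle, not that clinical-grade
accuracy would follow on real images.

## Benchmark sizes and numerical choices

The repository's fixed benchmark uses 60 images per class at
separability 0.7 with seed 0 (test suite) or the caller's seed
(acceptance script); classifier tuning uses 12 iterations per family
there. The monotonicity-in-separability check runs a reduced
configuration (24 images per class; chi-square top 300; prefix range
20–200 in steps of 5; three seeds averaged per separability level), and
the exchangeability check at separability 0 uses 20 images per class
with the leakage-safe fold-internal scope. These sizes are the package's
benchmark choices for a desk-scale, single-CPU run.

Tie-breaks are deterministic everywhere: ascending feature index for
equal scores or weights, smallest prefix for equal sweep errors.
Degenerate inputs raise explicit validation errors (single-class labels,
non-finite values, indivisible tilings, k larger than a training fold).
Floating-point conventions that affect discrete codes (the LPQ zero-sign
convention) are snapped explicitly rather than left to rounding noise.

## Known limitations

- Clinical-grade accuracy claims for this kind of pipeline rest on
  private fetal-ultrasound data; nothing here reproduces them, and the
  synthetic benchmark is deliberately easier than clinical data.
- The default selection scope leaks label information; use the
  fold-internal mode for honest error estimates.
- Binary classification only; no DICOM input; no anatomical detection
  or zoom localisation — inputs are assumed to be already-cropped
  regions of interest.
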