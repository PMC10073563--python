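# Methods

This note documents the models and numerical choices behind `braincad`: a
classical detection/classification pipeline for bright (T2-hyperintense)
brain lesions in 2-D MR slices, together with the synthetic phantom model
used to validate it.

## Retinex enhancement

**Model.** An observed slice is treated as `M = I · M₀`: true tissue signal
`M₀` times a smooth multiplicative intensity-inhomogeneity field `I` (the
MR "bias field", conventionally modeled as very smooth — near-polynomial
across the field of view). The tuned single-scale retinex response

```
R = log(M + ε) − log(g * (M + ε))        g(w,v) ∝ exp(−(w²+v²)/L²)^ξ
```

is the log-ratio of the image to its surround average; since a symmetric
kernel passes planar fields through unchanged, any near-planar `I` appears
in both terms and cancels exactly, independent of the surround width.

**Surround width (`kernel_size`, default 255).** The surround length scale
`L` is set to the image dimension. This is a deliberate regime choice: a
*small* surround (tens of pixels) turns the response into a band-pass edge
detector that flattens every structure larger than itself — lesions of
20–60 px diameter would vanish along with the brain/background contrast
that the downstream entropy threshold depends on. An image-scale surround
makes `g * M` a nearly global mean, so `R` is a monotone remapping of `M`
with the bias divided out: background stays dark, tissue mid, lesions
bright. The kernel is renormalized to unit sum after the ξ-power so that a
constant image yields exactly zero response (the defining retinex
contract); ξ = 1.5.

**Log floor (`epsilon`, default 100).** ε enters as `log(M + ε)` and
controls the transform's curvature. With ε ≈ 1 the logarithm's slope at
background level (~20) is an order of magnitude steeper than at tissue
level, so background noise dominates the rescaled output and destabilizes
the threshold. A floor on the order of the tissue intensity keeps the
transform near-linear below tissue level and log-compressive above it. The
default was fixed by a robustness analysis of the downstream threshold
(frequency of background|tissue mis-splits over 144 phantoms: 1/144 at
ε = 100 vs 3/144 at ε = 60), not by any image-quality aesthetic.

**Output mapping.** The real-valued response is linearly min–max rescaled
to [0, 255] and rounded half-up; a constant input is returned unchanged.
Borders are handled by reflective padding (avoids dark rims that would
create spurious histogram modes).

## Maximum-entropy segmentation

Kapur's criterion: for each grey level `t` with probability mass on both
sides, the foreground distribution `p(k)/P₁(t)` (k ≤ t) and background
distribution (k > t) each get a Shannon entropy; `t_opt` is the smallest
maximizer of their sum. Natural logarithms are used (the argmax is
base-invariant). Ties — including runs of empty grey levels, where H is
mathematically constant — are broken toward the smallest level, compared
with a 1e-12 tolerance because pairwise float summation makes
mathematically equal entropies differ in the last bit. The normalized
entropy `h_max/255` is reported as a diagnostic (`t_norm`) but is an
entropy, not a grey level, and is never used for masking. Foreground is
strictly-greater-than `t`: lesions are bright.

Morphological cleanup is binary opening with a disk followed by removal of
8-connected components below 50 px. The disk radius (supported range 8–12,
default 8) must stay below the semi-minor axis of the smallest lesion that
should survive, because opening deletes any structure that cannot contain
the disk; with lesions down to 10 px half-width, 8 is the safe end of the
range. Opening never adds foreground and the cleanup is idempotent.

A structural caveat: entropy thresholding always returns a *non-trivial*
split. On a lesion-free image it therefore separates brain from background
(~45–50 % foreground) rather than returning an empty mask. This is the
correct behavior for the downstream classifier — a whole-brain mask versus
a compact lesion mask is itself a strong class signal — but it means
segmentation quality (Dice) is only meaningful, and only reported, for
lesion-bearing images.

## NLBP texture descriptor

Parameters: radius r = 5, K = 24 circle samples (bilinear, k = 0 along the
+column axis, counter-clockwise), M = 4 anchors; feature length
M·(K+6) = 120. Anchors are the means of the M equal chunks of the sorted
central-pixel intensities (chunk length ⌊N/M⌋; up to M−1 trailing values
are dropped by the floor). The thresholding step function is the standard
LBP convention `f(d) = 1 iff d ≥ 0`, applied with a 1e-9 tolerance because
the four bilinear weights sum to one only to ~1e-16 — without it a
constant image fails its own uniform-pattern contract. The circular
transition count U is always even; codes are bit-sum (U ≤ 2), K+1…K+4
(U = 4, 6, 8, 10), K+5 otherwise. Because 90° rotations permute the K = 24
sample positions exactly, normalized descriptors are invariant under
90°/180°/270° image rotation to float precision.

In `full` mode the descriptor is computed on the enhanced image with
intensities zeroed outside the segmentation mask; central pixels remain
the full interior grid, and the anchors are computed from that same
(masked) pixel set. An empty or whole-brain mask is legitimate input and
produces the corresponding degenerate signature.

## Classifiers

GentleBoost is implemented in full: rounds of regression trees fitted to
the ±1 labels under the current example weights (at most `max_splits` = 10
splits, i.e. ≤ 11 regions). A region's fitted value — the weighted mean of
±1 labels — *is* the GentleBoost response `(g⁺−g⁻)/(g⁺+g⁻) ∈ [−1,1]`, so
the weak learner delegates to a standard weighted least-squares tree while
the boosting loop, weight update `g ← g·exp(−y·h(x))` with renormalization,
and the sign-of-sum decision rule are implemented here. The update
down-weights correctly classified points; a printed source formulation
with the opposite sign would up-weight them and diverge from the
boosting-literature algorithm, so the conventional sign is used. A zero
margin resolves to *pathological* — a deliberate clinical fail-safe toward
sensitivity. KNN (k = 3, Euclidean, majority vote) is implemented directly
with stable-sort tie-breaking toward earlier training rows. The RBF-SVM
(gamma = α, default 1/n_features; C = 1) and the 100-tree random forest
delegate to scikit-learn under these fixed hyperparameter contracts.

## Evaluation

Seven percentages from confusion counts: TPR, TNR, PPV,
F = 2·PPV·TPR/(PPV+TPR), DSC = 2TP/(2TP+FP+FN) (algebraically equal to F
on the same counts), AUC = (TPR+TNR)/2, accuracy. The (TPR+TNR)/2 form of
AUC is the single-operating-point ROC polygon area — the only AUC
derivable from hard labels, and the identity every row of the bundled
reference tables satisfies; a rank-based ROC AUC would require scores and
is deliberately not the default. Undefined ratios (zero denominators) are
reported as missing, never as 0. Values are rounded half-up (decimal, not
binary-float) to two places; cross-validation averages are means of the
*rounded* per-fold values, re-rounded — matching how the reference summary
tables are derived from their per-fold tables. Folds are stratified
(a 45:190-style imbalance makes unstratified 5-fold splits risk
single-class test sets) and shuffled by an explicit seed.

The bundled reference tables are embedded verbatim, misprints included; the
verifier recomputes every derivable cell (row AUC/F identities, column and
fold averages) at ±0.01 and classifies the ~15 internally inconsistent
cells (dropped decimal points such as 9111 → 91.11, truncation artifacts
of ±0.01–0.6) as known misprints rather than failures.

## Synthetic phantoms

Each phantom emulates a 256×256 8-bit T2 slice: background ≈ 20; a
centered brain ellipse (semi-axes ~0.36·W, 0.44·H, mild random
eccentricity) at mean 110 with Gaussian texture smoothed to 3 px
(amplitude 12); 0–3 non-overlapping tumor ellipses (semi-axes 10–30 px)
wholly inside the brain at +80 mean contrast with a shorter-range texture
(1.5 px smoothing), so texture as well as intensity carries class signal;
a multiplicative planar bias ramp of relative amplitude 0.2 across the
half-frame in a random direction; i.i.d. Gaussian noise σ = 8; clipping
and rounding to uint8. Labels: +1 iff any tumor. Corpora derive per-image
seeds from a master seed; generation is bit-exact reproducible.

The planar ramp is the deliberate bias model: it is the smooth,
scanner-realistic inhomogeneity that retinex provably corrects. What the
phantom does *not* emulate: anatomy (gyri, ventricles, skull/scalp — no
bright rim structures), Rician noise statistics, partial-volume effects,
multi-focal infiltrative lesion shapes, or inter-scanner intensity
variation. Passing tests on phantoms therefore demonstrates the
algorithmic contracts (bias cancellation, threshold behavior, descriptor
structure, end-to-end separability), not clinical performance.

## Problem sizes and variance

The end-to-end validation corpus is 60 phantoms (12 healthy / 48
pathological, preserving the ~1:4 imbalance of a 45/190 clinical
collection), chosen as the smallest corpus at which stratified 5-fold
cross-validation leaves both classes well represented in every fold. At
this size all three ablation modes classify at or near ceiling (58–60/60),
so single images separate the modes: across corpus seeds the full mode's
mean Dice is stable (93–97 %) and accuracy stays ≥ 95 %, but the
raw ≤ enhanced ≤ full accuracy ordering, while typical, can be broken by a
one-image flip (the reference tables show the same effect: their KNN
accuracy *drops* with enhancement). The residual failure mode is a rare
(~1/144) Kapur mis-split on a pathological image, which yields a
whole-brain mask and a healthy-looking signature.

## Known limitations

* Single global threshold: multi-focal lesions of very different
  brightness, or lesions on bright anatomical backgrounds, will defeat it.
* Entropy thresholding has no "no lesion" outcome; healthy-image masks are
  whole-brain by construction.
* The image-scale surround corrects smooth bias only; blotchy mid-scale
  inhomogeneity (scale comparable to lesions) is not correctable by any
  single-surround retinex without halo artifacts.
* AUC is the balanced-accuracy surrogate, not a rank statistic.
* 2-D only; no DICOM/NIfTI, no skull stripping, no registration.
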