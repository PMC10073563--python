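# braincad

A classical computer-aided-diagnosis (CAD) pipeline for detecting and
classifying brain tumors in 2-D T2-weighted MR slices, built for researchers
who want a fully inspectable, non-deep-learning baseline: every stage is a
small, testable function, and a seeded phantom generator makes the whole
pipeline reproducible without access to clinical data.

## The pipeline

1. **Enhancement — tuned single-scale retinex (TSSR).**
   The observed image is modeled as reflectance times a smooth illumination
   (bias) field. The enhanced image is the log-ratio of the image to its
   Gaussian-surround smoothed copy,

   `R(x,y) = log(M(x,y) + ε) − log((g * M)(x,y) + ε)`,

   with the surround `g(w,v) ∝ exp(−(w² + v²)/L²)^ξ` normalized to unit sum
   (ξ = 1.5, L = image dimension). A symmetric image-scale surround passes
   planar fields unchanged, so a smooth multiplicative bias cancels exactly
   in the log-ratio while the absolute background | tissue | lesion ordering
   survives. The response is min–max rescaled to an 8-bit image.

2. **Segmentation — Kapur maximum-entropy thresholding + morphology.**
   The grey level `t` maximizing `H(t) = H₁(t) + H₂(t)` — the Shannon
   entropies of the foreground (`k ≤ t`) and background (`k > t`) intensity
   distributions — binarizes the enhanced image; binary opening with a disk
   (radius 8) and small-object removal (< 50 px, 8-connected) cleans it.

3. **Features — non-local binary patterns (NLBP).**
   The intensities of all central pixels are sorted and cut into M = 4
   intervals; each interval's mean is an *anchor*. Every pixel's circular
   neighborhood (r = 5, K = 24 bilinear samples) is thresholded against each
   anchor and encoded by the extended rotation-invariant uniform (eriu2)
   rule: bit-sum for patterns with ≤ 2 circular transitions, one code each
   for 4/6/8/10 transitions, one catch-all — K + 6 = 30 codes per anchor.
   The descriptor is the concatenated, per-anchor-normalized histogram
   (4 × 30 = 120 values).

4. **Classification and evaluation.** Soft-margin SVM with RBF kernel
   `exp(−α|u−v|²)`, 3-NN Euclidean majority vote, 100-tree random forest,
   and GentleBoost (100 rounds of depth-limited weighted regression trees
   with leaf responses `(g⁺−g⁻)/(g⁺+g⁻)`, implemented here from first
   principles), scored by stratified 5-fold cross-validation with seven
   metrics: TPR, TNR, PPV, F-score, Dice (DSC), AUC = (TPR+TNR)/2, and
   accuracy.

Three ablation modes mirror the standard study design: `raw` (features
only), `enhanced` (TSSR + features), `full` (TSSR + segmentation + masked
features).

## Worked example

```python
import numpy as np
from braincad import (
    PhantomSpec, generate_phantom, tssr_enhance, segment,
    nlbp_features, metrics, confusion_from_masks,
)

image, truth, label = generate_phantom(PhantomSpec(n_tumors=1, seed=7))
enhanced = tssr_enhance(image)                 # image-scale retinex surround
mask, thr = segment(enhanced)                  # Kapur threshold + morphology
m = metrics(confusion_from_masks(mask, truth))
print(f"t_opt={thr.t_opt}  DSC={m.DSC}  TPR={m.TPR}  TNR={m.TNR}")

feat = nlbp_features(enhanced, mask)           # 120-dim masked descriptor
print(feat.normalized.shape, feat.normalized.sum())
```

prints

```
t_opt=183  DSC=95.57  TPR=91.51  TNR=100.0
(120,) 3.9999999999999996
```

i.e. the recovered tumor mask overlaps the ground truth closely (Dice
95.57 %, no false positives), and the descriptor is four unit-mass anchor
histograms.

The same flow from the shell:

```bash
braincad generate --n-healthy 2 --n-pathological 3 --seed 1 --out corpus/
braincad enhance corpus/images/phantom_0003.png --out enh.png
braincad segment enh.png --out mask.png --entropy-csv curve.csv
braincad run --mode full --seed 1 --n-healthy 12 --n-pathological 48 --out report/
braincad verify-tables
```

`braincad run` writes `features.csv`, per-fold and averaged metric tables,
a per-image segmentation table, and a run manifest. `braincad
verify-tables` recomputes every derivable cell of the bundled reference
result tables (row identities `AUC = (TPR+TNR)/2` and
`F = 2·PPV·TPR/(PPV+TPR)`, column and fold averages) and reports the
handful of known misprints in the source tables.

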