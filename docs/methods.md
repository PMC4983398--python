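# Methods

`octlbp` classifies spectral-domain OCT (SD-OCT) retinal volumes as normal
or containing diabetic macular edema (DME) from volumetric texture alone.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Pipeline

A volume is a stack of `d` B-scans indexed `(y, z, x)` — slice, depth row,
lateral column — with intensities in [0, 1]. Classification proceeds in
five stages:

1. **Preprocessing.** Each B-scan is denoised with non-local means (NLM),
   the retinal pigment epithelium (RPE) curvature is estimated and removed
   by a column-wise warp (flattening), and, optionally, all slices are
   warped to one shared altitude (alignment). The three chains NLM,
   NLM+flatten, NLM+flatten+align are the preprocessing variants the
   experiment presets sweep.
2. **Texture codes.** Rotation-invariant uniform local binary patterns
   (riu2 LBP) are computed per B-scan, or on the three orthogonal plane
   families of the volume (LBP-TOP). A pixel's raw code compares the `P`
   bilinearly interpolated samples on the circle of radius `R` against the
   center, `s(x) = 1` iff `x >= 0` (bit set on equality); codes with at
   most two circular transitions map to their popcount, all others to one
   non-uniform label, giving `P + 2` labels. Codes are undefined within
   `R` pixels of each border (masked, never padded).
3. **Mapping.** Code maps are partitioned into elements: *global* (one
   element per slice for LBP; the whole volume for LBP-TOP) or *local*
   (non-overlapping `m x m` patches / `m x m x m` subvolumes over the
   valid region, incomplete border cells dropped; `m = 7` by default).
   Each element becomes a `P + 2`-bin histogram; LBP-TOP elements
   concatenate the three plane histograms (x-z, x-y, y-z order).
4. **Representation.** Low level: the global elements' histograms
   concatenated (`d (P+2)` or `3 (P+2)` values). High level: a
   bag-of-visual-words — element histograms are quantized against a
   k-word codebook learned by k-means (k-means++ init, 300 iterations,
   tol 1e-4, single seeded restart) and the volume becomes the k-bin word
   occurrence histogram. Nearest-word assignment is Euclidean with ties
   to the lowest index.
5. **Classification and evaluation.** 3-NN, logistic regression, random
   forest / gradient boosting (100 unpruned trees), or RBF-SVM with
   `(C, gamma)` grid-searched over `C in 2^{-5..15}`, `gamma in
   2^{-15..3}` (step 2) by 5-fold stratified inner CV on the training
   fold. Evaluation is leave-one-patient-out: each fold holds out one
   DME-normal pair (seeded pairing; pooled metrics are pairing-invariant),
   trains on the rest — including the codebook, which is rebuilt per fold
   so nothing leaks from the held-out pair — and pooled predictions give
   SE = TP/(TP+FN), SP = TN/(TN+FP), ACC and F1 = 2TP/(2TP+FP+FN), with
   DME positive. Metrics are evaluated in exact rational arithmetic;
   SE/SP with empty denominators are reported as NaN with a warning, F1's
   zero-denominator case as 0 with a flag.

## Phantom

The synthetic generator makes every stage testable with exact ground
truth. It emulates the coarse structure of a macular SD-OCT cube, not its
optics:

* A layered bright band over dark background. The band bottom — the RPE,
  the landmark the flattening stage estimates — follows
  `z(x) = a x^2 + b x + c` per slice, with coefficients varying smoothly
  across slices (one sinusoidal period, +/- 2 px altitude wobble). The
  stored ground truth is exactly this bottom curve.
* Four layers (6, 10, 6, 8 px at intensities 0.55, 0.35, 0.50, 0.90)
  totalling ~30 px, a down-scaled analogue of the inner retina, nuclear
  layers, photoreceptors and RPE complex.
* Multiplicative gamma speckle of shape L = 4 (mean 1, variance 1/L), the
  standard coherent-imaging surrogate.
* DME volumes receive 5–9 non-overlapping ellipsoidal cysts (radii
  4–10 px, capped so they fit the geometry) plus up to 3 small bright
  exudate-like spots. Cysts model serous fluid: both the mean signal and
  the speckle amplitude inside them are damped by the contrast factor.
  The damping matters: riu2 LBP is invariant to monotone intensity
  scaling, so a lesion that only darkens the tissue is texture-invisible
  by construction; anechoic (smoother, darker) cysts are what real
  intraretinal fluid looks like and what the texture pipeline can see.
  Lesions keep the full RPE layer intact — cystoid spaces sit above it
  anatomically, and an effaced RPE floor would destroy the flattening
  landmark.

The default working geometry is `(d, H, W) = (32, 128, 256)`; the
clinical-scale 128 x 512 x 1024 cube is available through
`PhantomSpec(shape=...)` but is not needed to exercise any code path.

What the phantom does **not** emulate: A-scan optics, shadowing under
vessels or exudates, motion artefacts, inter-patient anatomical
variability beyond the quadratic curve family, or realistic lesion shape
statistics. Passing tests therefore demonstrate that the implementation
is correct and that the pipeline can separate texture-distinct classes
under LOPO-CV — not that it attains any particular accuracy on clinical
data.

## Numerical choices

* **NLM filter strength.** Defaults: 7 px patch, 21 px search window,
  `h = 0.8 * sigma_hat`. `sigma_hat` is 1.4826 x the median absolute
  high-frequency residual (slice minus 3x3 median) over *foreground*
  (Otsu) pixels. Speckle is multiplicative, so its absolute scale is set
  by the bright tissue; a global estimator tracks the dark background and
  yields an `h` too small to denoise the band at all.
* **Curve estimation.** Otsu threshold, 5x5 median filter, morphological
  closing then opening with a disk of radius 3, largest connected
  component, bottom-most row per column, least-squares quadratic fit.
  The structuring element must stay smaller than the thinnest structure
  to be preserved: a radius-5 disk (diameter 11) exceeds the 8 px RPE
  band and severs it next to large cysts, which is why 3 is the default.
  The fit fails loudly (naming the slice) if fewer than 3 columns
  survive cleaning.
* **Warping.** Per-column 1-D linear interpolation with zero fill;
  shifts `>= H` raise rather than wrap. Flatten-only warps each slice to
  its own `round(c)`; alignment warps to the shared reference row,
  default `round(0.6 H)` (any fixed altitude is equally valid).
* **LBP sampling.** `p = 0` at angle 0 (to the right), counter-clockwise;
  offsets within 1e-9 of the lattice are snapped so lattice-aligned
  angles are exact. Interpolated neighbours are compared to the center
  without rounding. Nearest-neighbour sampling is available behind a
  flag; bilinear is the default and the convention the tests' naive
  reference implements. The raw `2^P` code is never materialized for
  map computation — uniformity and popcount are accumulated from the
  sign planes directly, which keeps `P = 24` cheap.
* **BoW codebooks.** Fit on training-fold elements only and frozen for
  encoding. Training pools are subsampled (seeded, uniform) to at most
  100k element histograms before k-means; a 30-volume training fold
  carries ~620k local patches, and the subsample changes the dictionary
  negligibly while keeping per-fold clustering tractable. `build`
  methods: full k-means, k-means++ seeding only (the cheap randomized
  codebook used for word-count sweeps), or uniform sampling of training
  histograms.
* **Descriptors for classification.** The experiment presets L1-normalize
  descriptors (per constituent histogram for low-level, whole vector for
  BoW), the standard practice for count features feeding distance-based
  classifiers; raw counts remain the default at the library surface.
* **Determinism.** Every random component (phantom, pairing, subsampling,
  k-means, forests, CV shuffling) is seeded from the experiment seed;
  rerunning a config reproduces the results table bitwise.

## Known limitations

* The phantom's class difference is concentrated in cyst texture; global
  mappings (one histogram per slice) dilute it and separate less well
  than local mappings — consistent with patch-based representations
  being the stronger configuration, but driven here by construction.
* `estimate_retina_curve` assumes the retina is the largest bright
  component and that its bottom boundary is quadratic; pathologies that
  detach or split the RPE would need presegmentation, which is out of
  scope.
* LBP-TOP at `R = 3` needs all three dimensions `> 7`; very thin cubes
  fall back to errors, not padding.
* The SVM grid search is nested (per outer fold), which is the
  leakage-free reading but makes per-fold hyper-parameters vary; only
  pooled metrics are reported.
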