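# octlbp

Texture-based classification of spectral-domain OCT (SD-OCT) retinal
volumes as **normal** vs. **DME** (diabetic macular edema), using local
binary patterns in 2-D and on three orthogonal planes, with a synthetic
phantom generator that makes the whole pipeline testable without clinical
data.

It is aimed at researchers in retinal image analysis who want a
reproducible, fully seeded reference pipeline for volumetric texture
classification — and a ground-truthed phantom to validate each stage
against.

## The method

A volume is a stack of `d` B-scans indexed `(y, z, x)`. Five stages:

1. **Preprocess** — per-B-scan non-local-means despeckling; retina
   flattening (Otsu → median → morphological cleaning → largest component
   → quadratic fit `z(x) = a x² + b x + c` of the RPE bottom boundary →
   column-wise warp); optional alignment of all slices to one altitude.
2. **LBP / LBP-TOP** — rotation-invariant uniform (riu2) codes
   `LBP_{P,R} = Σ_p s(g_p − g_c) 2^p`, `s(x) = 1` iff `x ≥ 0`, with
   uniform patterns labelled by popcount and all others merged: `P + 2`
   labels for `P ∈ {8, 16, 24}`, `R ∈ {1, 2, 3}`. LBP-TOP applies this
   independently on the (x-z), (x-y) and (y-z) plane families.
3. **Mapping** — *global* (per-slice / whole-volume) or *local*
   (non-overlapping 7×7 patches / 7×7×7 subvolumes) partition of the code
   maps into elements, one `P+2`-bin histogram per element.
4. **Representation** — *low level*: concatenated global histograms
   (`d(P+2)` for LBP, `3(P+2)` for LBP-TOP); *high level*: bag of visual
   words over a k-means codebook (histogram of nearest-word counts).
5. **Classify & evaluate** — 3-NN, logistic regression, random forest,
   gradient boosting (100 unpruned trees) or grid-searched RBF-SVM, under
   leave-one-patient-out cross-validation (one DME–normal pair held out
   per fold, codebooks refit per training fold), reporting
   `SE = TP/(TP+FN)`, `SP = TN/(TN+FP)`, `ACC`, `F1 = 2TP/(2TP+FP+FN)`.

The phantom generates curved, layered, speckled OCT-like cubes; DME cubes
carry anechoic ellipsoidal cysts (darker *and* smoother — riu2 LBP is
invariant to pure intensity scaling, so texture is the signal) plus small
bright exudate-like spots, with the exact per-slice curve coefficients and
the cyst voxel mask recorded as ground truth. See `docs/methods.md`.

## Worked example

```python
import octlbp as ol
from octlbp.experiment import apply_preprocessing, extract_features

spec = ol.PhantomSpec(lesion=ol.LesionSpec(contrast=0.8))
cohort = [v for v, _ in ol.generate_dataset(spec, n_per_class=16, seed=42)]
pre = [apply_preprocessing(v, ["nlm", "flatten"]) for v in cohort]
feats = extract_features(pre, "lbp", ol.LBPParams(8, 1),
                         ol.MappingSpec("local", m=7))
report = ol.evaluate(
    feats,
    ol.ClassifierSpec(family="svm_rbf", seed=42),
    ol.RepresentationSpec(kind="bow", k=70, build="kmeans", normalize=True),
    seed=42,
)
m = report.metrics
print(f"SE={m.se:.3f} SP={m.sp:.3f} ACC={m.acc:.3f} F1={m.f1:.3f}")
print(report.pooled)
```

Output:

```
SE=0.938 SP=1.000 ACC=0.969 F1=0.968
ConfusionCounts(TP=15, TN=16, FP=0, FN=1)
```

Read: of the 16 held-out DME patients, 15 were detected (sensitivity
0.938) and no normal patient was misclassified (specificity 1.0) — the
pipeline recovers the texture difference that the high-contrast cysts
(contrast 0.8) imprint on the phantom cohort.

The same experiment, as a sweep over preprocessing chains and classifiers,
runs from a YAML config:

```bash
octlbp phantom --n-per-class 4 --out cohort/ --seed 7
octlbp run --config src/octlbp/configs/experiment2.yaml
```

with `experiment1/2/3.yaml` presets covering the word-count sweep, the
high-level (BoW) classifier comparison and the low-level (concatenated
histogram) comparison. Individual stages are also exposed
(`octlbp preprocess | extract | represent | evaluate`).

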