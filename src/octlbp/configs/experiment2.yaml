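# High-level (BoW, full k-means codebooks) representation with the four
# non-linear/linear classifiers, every preprocessing chain. Scaled to a
# small phantom cohort.
seed: 7
dataset:
  phantom:
    n_per_class: 4
preprocessing:
  - [nlm]
  - [nlm, flatten]
  - [nlm, flatten, align]
features:
  - {feature: lbp, P: 8, R: 1}
  - {feature: lbptop, P: 8, R: 1}
mapping: {mode: local, m: 7}
representation: {kind: bow, k: 70, build: kmeans, normalize: true}
classifiers: [knn, random_forest, gradient_boosting, svm_rbf]
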