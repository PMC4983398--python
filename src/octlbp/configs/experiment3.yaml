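# Low-level (concatenated global histograms) representation with the four
# classifiers, every preprocessing chain. Scaled to a small phantom cohort.
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
mapping: {mode: global}
representation: {kind: histogram, normalize: true}
classifiers: [knn, random_forest, gradient_boosting, svm_rbf]
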