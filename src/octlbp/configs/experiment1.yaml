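# Word-count sweep: randomized (k-means++ seeded) codebooks, logistic
# regression, every preprocessing chain. Scaled to a small phantom cohort;
# edit k under `representation` to walk the sweep
# k in {10,20,...,100,200,...,500,1000}.
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
representation: {kind: bow, k: 70, build: kmeans_pp_init_only, normalize: true}
classifiers: [logistic]
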