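# Homogeneous screening dataset: 10 activity classes whose intra-class
# mean pairwise Tanimoto targets echo a structurally homogeneous benchmark
# subset (~0.23-0.36), plus background decoys.  Feature dimension is kept
# at 64 so the bundled reduced autoencoder presets (64->32->16) apply.
feature_dim: 64
n_background: 1000
density: 0.1
intensity: 3.0
seed: 0
classes:
  - {label: hom01, size: 100, target_similarity: 0.30}
  - {label: hom02, size: 100, target_similarity: 0.36}
  - {label: hom03, size: 100, target_similarity: 0.29}
  - {label: hom04, size: 100, target_similarity: 0.32}
  - {label: hom05, size: 100, target_similarity: 0.26}
  - {label: hom06, size: 100, target_similarity: 0.30}
  - {label: hom07, size: 100, target_similarity: 0.27}
  - {label: hom08, size: 100, target_similarity: 0.34}
  - {label: hom09, size: 100, target_similarity: 0.23}
  - {label: hom10, size: 100, target_similarity: 0.31}
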