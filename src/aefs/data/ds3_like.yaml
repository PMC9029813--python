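# Heterogeneous screening dataset: 10 structurally diverse activity
# classes (intra-class mean pairwise Tanimoto ~0.10-0.13) plus background
# decoys; the hard case for similarity searching.
feature_dim: 64
n_background: 1000
density: 0.1
intensity: 3.0
seed: 0
classes:
  - {label: het01, size: 100, target_similarity: 0.11}
  - {label: het02, size: 100, target_similarity: 0.10}
  - {label: het03, size: 100, target_similarity: 0.10}
  - {label: het04, size: 100, target_similarity: 0.13}
  - {label: het05, size: 100, target_similarity: 0.12}
  - {label: het06, size: 100, target_similarity: 0.10}
  - {label: het07, size: 100, target_similarity: 0.11}
  - {label: het08, size: 100, target_similarity: 0.11}
  - {label: het09, size: 100, target_similarity: 0.12}
  - {label: het10, size: 100, target_similarity: 0.11}
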