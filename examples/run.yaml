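# Run config for `covnet compare` (region names must match the cohort header)
cohort_path: cohort.csv
networks:
  all: [R1, R2, R3, R4, R5, R6, R7, R8, R9, R10, R11, R12]
comparisons:
  - [HC, AD_no_epilepsy]
  - [HC, AD_epilepsy]
  - [AD_no_epilepsy, AD_epilepsy]
permutation:
  n_permutations: 1000
  seed: 0
  alpha: 0.05
  ci_level: 0.95
distance_convention: inverse-weight
include_average_degree: true
output_dir: results
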