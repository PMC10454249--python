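# Synthetic cohort spec for `covnet generate`
region_count: 12
seed: 7
mean_volumes: 3000.0
age_effect: -8.0
sex_effect: 120.0
noise_sd: 250.0
sex_balance: 0.47
age_distribution: {mean: 69.9, sd: 11.9}
groups:
  HC:
    size: 45
    correlation: {style: modular, strength: 0.55, block_size: 4}
  AD_no_epilepsy:
    size: 56
    correlation: {style: modular, strength: 0.45, block_size: 4}
  AD_epilepsy:
    size: 25
    correlation: {style: modular, strength: 0.30, block_size: 4}
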