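# Cohort-like simulation scenario: the reference haplotype frequency table
# (two-SNP haploallele x haploid copy count; printed values, normalized on
# load) and the pooled case-control effect size (OR 1.459 for low copies).
n_individuals: 1792
case_log_odds_intercept: -0.325
low_copy_odds_ratio: 1.459
onset_median_years: 1.5
onset_shift: -0.5
onset_log_sd: 1.0
onset_missing_rate: 0.25
ct_noise_sd: 0.1
efficiency: 1.94
replicates: 3
expression_noise_sd: 0.5
haplotype_frequencies:
  "CC|1": 0.0102
  "GT|1": 0.4984
  "AT|1": 0.0491
  "CC|2": 0.0632
  "GT|2": 0.0449
  "AT|2": 0.2312
  "CC|3": 0.0765
  "GT|3": 0.0046
  "AT|3": 0.0220
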