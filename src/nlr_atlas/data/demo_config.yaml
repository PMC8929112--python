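# End-to-end demo: every stage on synthetic inputs, seconds of runtime.
outdir: demo_out
seed: 7
simulate:
  chrom_lengths: {1A: 2000000, 1B: 2000000}
  n_genes: 120
  nlr_fraction: 0.15
  telomere_bias: 3.0
  n_sites: 4000
  group_specs:
    - {name: wild, n_samples: 12, divergence: 0.2}
    - {name: domesticated, n_samples: 12, divergence: 0.2}
  sweep_regions:
    - {chrom: 1A, start: 800001, end: 1000000, reduction: 0.05}
  omega_settings:
    - {omega: 0.2, branch_length: 0.3, n_pairs: 30, n_codons: 120}
  expression_design_auto:
    experiments: [fhb, powdery_mildew]
    timepoints: [24, 48]
    tissues: [leaf]
    n_replicates: 3
  expression_fold: 8.0
  responsive_genes: [G000001, G000002, G000003, G000004]
scan:
  bit_threshold: 25.0
atlas:
  window_size: 200000
  min_cluster: 2
kaks:
  rate: 6.1e-9
  bin_width: 0.04
ors:
  promoter_length: 2000
sweep:
  window_size: 50000
  step: 5000
  quantile: 0.95
  comparisons:
    - {name: domestication, numerator: wild, denominator: domesticated}
express:
  k: 4
  fold: 2.0
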