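# Small end-to-end demo run (completes in well under a minute on one CPU).
seed: 11
reference:
  lengths: {RNA1: 800}
exposure:
  default: 0.15
  barriers:
    - {region: "RNA1:151-250", baseline: 0.15, amplitude: 0.6, midpoint: 55, steepness: 2}
temperatures: [50, 52.5, 55, 57.5, 60, 62.5, 65, 67.5, 70, 75]
library:
  n_fragments: 2000
  p_term: 0.16666666666666666   # 1:5 terminator:extender ratio
  min_length: 20
  max_read_length: 75
  p_error: 0.0
  dup_mean: 1.5
  dup_model: poisson
crosslink:
  temperature: 50
  replicates: 2
  n_fragments: 4000
  p_background: 0.01
  n_sites: 10
  p_xl: 0.4
regions: ["RNA1:151-250", "RNA1:400-500"]
thresholds:
  min_depth: 50
  signal_cutoff: 1.5
  trend_rho: 0.7
  trend_range: 0.25
  coverage_window: 50
  priming_window: 15
compress_fastq: true
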