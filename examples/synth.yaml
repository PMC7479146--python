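# Example generator settings for `ringlife synth --config examples/synth.yaml`
# (any omitted field keeps its black-spruce-anchored default)
synth:
  n_trees: 1000
  n_sites: 25
  max_diameter_mean: 300.0   # mm
  max_diameter_sd: 23.0      # mm; 99th-pct attained size ~353 mm
  ar1_coef: 0.5
  noise_sd: 0.2
  temp_growth_slope: 0.1     # per degC multiplier on growth speed
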