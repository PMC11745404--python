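out_dir: pipeline_out
panel_path: examples/fixture_panel.csv
calibration_path: examples/calibration.csv
seeds:
  simulate: 101
  observation: 202
bins: {}
strata_keys: []
trend:
  min_group: 50
noise:
  min_n: 20
simulate:
  dt: 0.1
  n_steps: 990
  n_samples: 2000
  record_every: 10
warming:
  rate: 0.04
area_per_bin_ha: 1000.0
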