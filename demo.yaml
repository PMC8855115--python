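# Demonstration pipeline config: synthetic two-arm fractionation study,
# scaled to run in a few minutes on one CPU.
seed: 1
dt: 0.05            # Euler step (hr); 0.01 reproduces the reference numerics
gate_sharpness: 1.0

generator:
  cell_lines: ["9L", "C6"]
  replicates_per_condition: 6
  noise_cv: 0.21
  schedules: ["16x2", "16x3", "16x4", "20x2", "20x3", "20x4"]
  horizon: 330
  generating_model: 3

split:
  fraction: 0.75

selection:
  sample_count: curves
  n_starts: 1
  max_nfev: 150

calibration:
  model: 3
  n_starts: 2
  max_nfev: 400
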