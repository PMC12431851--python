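# Small end-to-end demonstration run: AFM elastography on a striped
# calibration substrate, biased-walker migration on the shallow gradient,
# and an end-point durotaxis assay on the stripes.  Completes in well under
# a minute on one CPU.
seed: 7
elastography:
  field: fibrotic
  extent_um: [200.0, 200.0]
  pitch_um: 5.0
  noise_frac: 0.02
  n_slopes: 50
  smooth_window: 3
  min_prominence_Pa: 2500.0
  detect_smooth_sigma_px: 0.0
migration:
  pattern: linear_gradient
  n: 75
  bias_strength: 0.05
  duration_s: 21600
  frame_interval_s: 300
assay:
  pattern: step_stripes
  n: 150
  bias_strength: 0.05
  duration_s: 86400
  frame_interval_s: 600
  baseline_h: 4.0
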