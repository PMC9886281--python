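name: stable_sls_frap
version: 1
kind: frap_movie
description: >
  Near-immobile Z-disc label in living larval muscle: 95% immobile pool,
  5% mobile pool with a 5 min time constant, deep bleach, 1 min frame
  interval over 30 min (3 pre-bleach frames + 30 post-bleach frames).
pixel_size_um: 0.2
geometry_preset: larval
n_periods: 8
field:
  margin_um: 3.0
  muscle_width_um: 16.0
  background_level: 10.0
  baseline_fraction: 0.2
frap:
  immobile_fraction: 0.95
  recovery_tau_s: 300.0
  bleach_depth: 0.8
  bleach_roi_um: [5.0, 10.0, 15.0, 30.0]
  frame_interval_s: 60.0
  n_frames: 33
  n_prebleach: 3
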