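name: degrad_larval
version: 1
kind: degrad_pair
description: >
  Control vs knockdown larval muscle pair for the Z-disc channel: band
  amplitude reduced by 80% in the treated image, identical background.
  Quantified with a 10x10 um background rectangle and 100 band rectangles.
pixel_size_um: 0.1
geometry:
  sarcomere_length_um: 8.5
  psf_sigma_um: 0.25
  n_periods: 5
  channels:
    Nano2:
      kind: point
      offsets_um: [0.0]
      amplitude: 100.0
field:
  margin_um: 2.0
  muscle_width_um: 5.0
  background_level: 20.0
degrad:
  reduction_factor: 0.8
  channel: Nano2
  n_rois: 100
  roi_size_px: [10, 5]
  background_roi_um: [0.0, 0.0, 1.6, 10.0]
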