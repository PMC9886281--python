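name: larval_projectin
version: 1
kind: striated_profile
description: >
  Larval muscle stained for the thick-filament protein with N- and
  C-terminal channels: both render as blocks on each half of the A-band;
  the C-terminal channel (Nano37) sits 0.3 um closer to the M-band
  (midpoint of the 8.5 um period at 4.25 um).
pixel_size_um: 0.05
geometry:
  sarcomere_length_um: 8.5
  psf_sigma_um: 0.15
  n_periods: 6
  channels:
    Nano30:
      kind: block
      offsets_um: [[2.2, 3.6], [4.9, 6.3]]
      amplitude: 90.0
    Nano37:
      kind: block
      offsets_um: [[2.5, 3.9], [4.6, 6.0]]
      amplitude: 90.0
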