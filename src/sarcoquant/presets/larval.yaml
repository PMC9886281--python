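name: larval
version: 1
kind: striated_profile
description: >
  Relaxed larval body-wall muscle: 8.5 um sarcomeres, Z-disc channel as a
  single band at the Z-disc, partner channel at +/- 2.0 um marking the two
  ends of the long I-band.
pixel_size_um: 0.05
geometry:
  sarcomere_length_um: 8.5
  psf_sigma_um: 0.25
  n_periods: 10
  channels:
    Nano2:
      kind: point
      offsets_um: [0.0]
      amplitude: 100.0
    Nano42:
      kind: point
      offsets_um: [2.0, -2.0]
      amplitude: 80.0
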