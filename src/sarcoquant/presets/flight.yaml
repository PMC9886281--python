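name: flight
version: 1
kind: striated_profile
description: >
  Indirect flight muscle: ~3.2 um sarcomeres with a tiny I-band, so the two
  channels form a single overlapping band at the Z-disc (separation far
  below the PSF width).
pixel_size_um: 0.05
geometry:
  sarcomere_length_um: 3.2
  psf_sigma_um: 0.15
  n_periods: 10
  channels:
    Nano2:
      kind: point
      offsets_um: [0.0]
      amplitude: 100.0
    Nano42:
      kind: point
      offsets_um: [0.05, -0.05]
      amplitude: 80.0
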