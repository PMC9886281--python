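name: leg
version: 1
kind: striated_profile
description: >
  Leg muscle: ~3.0 um sarcomeres with a short but resolvable I-band; the
  partner channel forms a doublet around each Z-disc band.
pixel_size_um: 0.05
geometry:
  sarcomere_length_um: 3.0
  psf_sigma_um: 0.15
  n_periods: 10
  channels:
    Nano2:
      kind: point
      offsets_um: [0.0]
      amplitude: 100.0
    Nano42:
      kind: point
      offsets_um: [0.35, -0.35]
      amplitude: 80.0
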