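name: attenuation_antibody
version: 1
kind: depth_stack
description: >
  Flight-muscle z-stack with the steep attenuation of a large two-layer
  label that penetrates poorly. Decay length 6 um; pairs with
  attenuation_nanobody (15 um) at the documented 2.5-fold contrast.
pixel_size_um: 0.05
geometry_preset: flight
attenuation:
  label: antibody
  decay_length_um: 6.0
  i0: 100.0
  z_step_um: 1.0
  n_slices: 10
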