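name: attenuation_nanobody
version: 1
kind: depth_stack
description: >
  Flight-muscle z-stack with the shallow intensity attenuation of a small
  label that penetrates the tissue well. Decay length 15 um; pairs with
  attenuation_antibody (6 um) at the documented 2.5-fold contrast.
pixel_size_um: 0.05
geometry_preset: flight
attenuation:
  label: nanobody
  decay_length_um: 15.0
  i0: 100.0
  z_step_um: 1.0
  n_slices: 10
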