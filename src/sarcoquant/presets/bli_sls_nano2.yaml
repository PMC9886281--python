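name: bli_sls_nano2
version: 1
kind: bli_series
description: >
  High-affinity 1:1 sensorgram series: kon 1e6 /M/s, koff 1e-5 /s
  (KD 10 pM), 0.4 nm saturation signal, 200 s association / 900 s
  dissociation, four log-spaced analyte concentrations. The source
  experiment shows its concentrations only graphically, so this series is
  a documented convention.
bli:
  kon_per_M_s: 1.0e6
  koff_per_s: 1.0e-5
  rmax_nm: 0.4
  t_assoc_s: 200.0
  t_dissoc_s: 900.0
  sample_interval_s: 1.0
  concentrations_M: [1.0e-9, 3.0e-9, 1.0e-8, 3.0e-8]
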