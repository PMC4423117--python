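{
  "eta0": 0.00028,
  "eta1": 0.002,
  "b0": 0.2,
  "d0": 1.0,
  "eta_b": 4e-05,
  "alpha_s": 0.002,
  "alpha_b": 5e-05,
  "alpha_c": 0.0002,
  "alpha_d": 0.000125,
  "k_plus": 5.0,
  "k_minus": 5e-05,
  "D_s": 1.5e-13,
  "D_b": 7.8e-13,
  "D_c": 2.5e-09,
  "l_x": 0.0017,
  "l_y": 0.002,
  "complex_cleavage_rate": "alpha_s"
}
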