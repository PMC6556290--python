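{
 "parameters": {
  "a1": 15.0,
  "a2": 40.0,
  "a3": 100.0,
  "alpha0": -3.359,
  "alpha1": 0.03668,
  "beta0": -8.96,
  "beta1": 0.20481,
  "beta2": 2e-05,
  "beta3": 0.00836,
  "det1": 0.5487,
  "det2": 0.3231,
  "det3": 0.0386,
  "det4": 0.3432,
  "input_scale": "rate",
  "mort2": 0.1515,
  "mort3": 0.3597,
  "mort4": 0.5647,
  "onset_form": "piecewise_offset",
  "p_md_to_sd": 0.1538,
  "p_sd_to_u1": 0.2094,
  "p_u1_u2": 0.1538,
  "p_u2_u3": 0.2094,
  "p_u3_u4": 0.4665
 },
 "sd": {
  "alpha0": 0.171,
  "alpha1": 0.0095,
  "beta0": 0.461,
  "beta1": 0.01815,
  "beta2": 0.0,
  "beta3": 0.00134,
  "det1": 0.137175,
  "det2": 0.080775,
  "det3": 0.00965,
  "det4": 0.0858,
  "p_md_to_sd": 0.03845,
  "p_u1_u2": 0.03845,
  "p_u2_u3": 0.05235,
  "p_u3_u4": 0.116625
 }
}
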