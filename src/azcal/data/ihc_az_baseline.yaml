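# Baseline inner-hair-cell active-zone model: "physiological" buffering
# (0.8 mM EGTA + 0.4 mM BAPTA) with 25 uM OGB-5N indicator and a
# 430 x 67 nm cluster of 120 channels.
# Units: nm (geometry), ns (time step), ms (duration), uM (concentrations),
# um^2/ms (D), uM^-1 ms^-1 (k_on), pA (current).
extent_nm: [800, 800, 300]
h_nm: 5
dt_ns: null        # null = largest stable explicit step
duration_ms: 1.0
ca_rest_uM: 0.05
buffers:
  - {name: fixed,     D: 0.0,  K_D: 4.859,   k_on: 1.375,  total: 610}
  - {name: EGTA,      D: 0.14, K_D: 0.071,   k_on: 0.0105, total: 800}
  - {name: BAPTA,     D: 0.14, K_D: 0.17,    k_on: 0.45,   total: 400}
  - {name: OGB-5N,    D: 0.1,  K_D: 195.0,   k_on: 0.25,   total: 25, fluorescent: true}
  - {name: ATP,       D: 0.14, K_D: 2200.0,  k_on: 0.013,  total: 68}
  - {name: gluconate, D: 0.2,  K_D: 57000.0, k_on: 0.1,    total: 130000}
cluster:
  n: 120
  length_nm: 430
  width_nm: 67
  min_nn_nm: 10
  i_single_pA: 0.137
  p_open: 0.4
  seed: 0
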