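backend: morris_lecar
n_neurons: 100
duration_s: 9.0
dt_ms: 0.025
dl: 0.1
jitter_sd: 0.0
record_stride_ms: 1.0
gate:
  alpha_s: 0.1
  beta_s: 0.05
  theta_s: 0.2
  sigma_s: 0.02
coupling:
  g_bar_s: 0.4
  v_rev_syn: -0.85
  sigma_g: 0.5
  c_n: 2.0584
  v_scale: 1.0
  i_scale: 1.0
noise:
  D_noise: 1.0e-05
  tau_noise: 5.0
  seed: 0
seeds:
  lattice: 1835504127
  noise: 1731038949
  init: 1320224556
  interpop: 182557857
neuron_ml:
  g_ca: 1.0
  g_k: 2.0
  g_l: 0.5
  v_ca: 1.0
  v_k: -0.7
  v_l: -0.5
  v1: -0.01
  v2: 0.15
  v3: 0.1
  v4: 0.145
  C: 1.0
  phi: 1.15
  v_star: -0.22
  alpha: 0.0
  tau_j: 10.0
  eps_j: 0.002
  eps_sd: 2.0e-05
  s1: 1.0
stimulation:
  mode: quad
  train:
    freq_hz: 130.0
    t_pos_ms: 0.2
    t_neg_ms: 3.0
    amp_pos: 9.0
  window_s:
  - 4.5
  - 9.0
  c_s: 0.1
  decay_len: 0.35
  weight: 1.0
  slow_weight: 0.008
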