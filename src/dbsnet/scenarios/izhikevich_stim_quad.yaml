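backend: izhikevich
n_neurons: 225
duration_s: 6.5
dt_ms: 0.1
dl: 0.1
jitter_sd: 0.1
record_stride_ms: 1.0
gate:
  alpha_s: 0.1
  beta_s: 0.05
  theta_s: 0.2
  sigma_s: 0.02
coupling:
  g_bar_s: 0.2
  v_rev_syn: -0.8
  sigma_g: 0.5
  c_n: 2.1765
  v_scale: 0.01
  i_scale: 5.0
noise:
  D_noise: 1.0e-05
  tau_noise: 5.0
  seed: 0
seeds:
  lattice: 1835504127
  noise: 1731038949
  init: 1320224556
  interpop: 182557857
neuron_izh:
  a: 0.02
  b: 0.2
  c_reset: -50.0
  d: 0.7
  drive: 4.0
  drive_sd: 0.05
  spike_cut: 30.0
stimulation:
  mode: quad
  train:
    freq_hz: 130.0
    t_pos_ms: 0.2
    t_neg_ms: 3.0
    amp_pos: 256.0
  window_s:
  - 3.0
  - 6.5
  c_s: 0.1
  decay_len: 0.15
  weight: 50.0
  slow_weight: 0.0
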