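# Asynchronous regime: weak recurrent excitation, strong background noise.
# sigma values are 2/sqrt(2) and 3/sqrt(2).
name: asynchronous
N_E: 80
N_I: 20
tau_m: 20.0
E_E: 6.5
E_I: -0.5
tau_ref: 2.0
v_reset: 0.0
alpha_E: 1.0
alpha_I: 2.0
tau_r_E: 1.0
tau_d_E: 5.0
tau_r_I: 2.0
tau_d_I: 10.0
W_EI: 10.0
W_IE: 5.0
W_EE: 0.5
W_II: 5.0
sigma_E: 1.4142135623730951
sigma_I: 2.1213203435596424
p_conn:
  EE: 0.40
  EI: 0.35
  IE: 0.20
  II: 0.40
theta_cv: 0.2
theta_cdf_lo: 0.05
theta_cdf_hi: 0.95
seed: 0
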