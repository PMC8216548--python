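# Metronome with true tempo near the top of a wide tempo prior.
period: 1.0
theta_true: 1.3
n_events: 6
lam: 0.4
v: 0.001
lambda_0: 0.01
dt: 0.001
sigma: 0.05
sigma_theta: 0.03
mu_phi_0: 0.0
mu_theta_0: 1.0
V_pp_0: 0.04
V_tt_0: 0.09
t_end: 4.9
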