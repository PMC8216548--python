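# Filled vs empty strongly expected interval.
subdivision: 0.25
t_start: 0.25
t_end_interval: 2.25
lam: 1.0
v: 0.0004
lambda_0: 0.02
lambda_0_high: 4.0
dt: 0.001
sigma: 0.1
sigma_theta: 0.1
mu_phi_0: 0.0
V_pp_0: 0.0001
V_tt_0: 0.01
t_end: 2.5
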