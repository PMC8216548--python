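# Single-peak event-response sweeps.
phi_1: 0.5
mu_t: 0.4
V_t: 0.01
lambda_1: 1.0
v_1: 0.0025
lambda_0_values: [0.0, 0.5]
mu_t_range: [0.0, 1.0]
V_t_range: [0.001, 0.05]
lambda_1_range: [0.2, 5.0]
v_1_range: [0.0005, 0.02]
grid_n: 41
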