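# Heavily syncopated swung rhythm; baseline fails, rescues track.
cycle: 1.0
swing_ratio: [3, 2]
strong_lam: 0.4
strong_v: 0.0004
weak_lam: 0.08
weak_v: 0.0016
lambda_0: 0.01
n_cycles: 7
occupancy: [0, 1, 3, 7, 9, 11, 12]
dt: 0.001
sigma: 0.12
sigma_low: 0.05
mu0: 0.0
V0: 0.0001
t_end: 6.5
tap_period: 0.5
tap_lam: 0.4
tap_v: 0.0004
tap_lambda_0: 0.01
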