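# Phase shift at the fourth metronome event, swept over IOI.
ioi_grid: [0.3, 0.45, 0.6, 0.75, 0.9, 1.05, 1.2]
shift_fraction: -0.1
lam: 0.2
v: 0.001
lambda_0: 0.01
dt: 0.001
sigma: 0.04
sigma_theta: 0.04
V_pp_0: 0.0001
V_tt_0: 0.0025
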