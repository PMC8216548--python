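# Swung-eighth-note tracking; calibrated defaults (frozen).
cycle: 1.0
swing_ratio: [3, 2]
strong_lam: 0.2
strong_v: 0.0004
weak_lam: 0.1
weak_v: 0.0016
lambda_0: 0.1
n_cycles: 5
# grid positions: even = strong (k*cycle), odd = weak (k*cycle + 0.6)
occupancy: [0, 1, 2, 4, 5, 6, 7, 8]
shift_index: 3
shift_delta: -0.15
dt: 0.001
sigma: 0.06
mu0: 0.0
V0: 0.0001
t_end: 4.5
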