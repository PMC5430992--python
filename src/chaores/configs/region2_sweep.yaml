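# Bifurcation diagram + Lyapunov exponents over d in the tangent /
# intermittency region (a=0.2, b=2, c=-56, I=-99), signal-free.
name: region2_sweep
kind: sweep_d
params: {a: 0.2, b: 2.0, c: -56.0, d: -12.0, I: -99.0}
signal: {A: 0.0, f0: 0.1}
sweep: {d_min: -15.5, d_max: -11.0, d_step: 0.005}
metrics: {settle: 2000, n_segments: 50, tail_keep: 64}
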