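# Bifurcation diagram + Lyapunov exponents over d in the period-doubling
# region (a=0.02, b=0.2, c=-55, I=10), signal-free.
name: region1_sweep
kind: sweep_d
params: {a: 0.02, b: 0.2, c: -55.0, d: 0.85, I: 10.0}
signal: {A: 0.0, f0: 0.1}
sweep: {d_min: 0.82, d_max: 0.92, d_step: 0.0005}
metrics: {settle: 2000, n_segments: 50, tail_keep: 64}
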