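# Maximum Lyapunov exponent over the (c, d) plane around the chaotic-spiking
# parameter set (a=0.2, b=2, I=-99).  Scaled-down grid.
name: fig1b_map
kind: map_cd
params: {a: 0.2, b: 2.0, c: -56.0, d: -16.0, I: -99.0}
signal: {A: 0.0, f0: 0.1}
sweep: {c_min: -60.0, c_max: -50.0, c_step: 0.25, d_min: -20.0, d_max: -8.0, d_step: 0.3}
metrics: {n_segments: 30}
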