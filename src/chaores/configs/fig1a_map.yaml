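# Maximum Lyapunov exponent over the (c, d) plane around the RS/IB/CH
# parameter sets (a=0.02, b=0.2, I=10).  Coarse default grid; tighten
# c_step/d_step for a full-resolution map.
name: fig1a_map
kind: map_cd
params: {a: 0.02, b: 0.2, c: -55.0, d: 1.0, I: 10.0}
signal: {A: 0.0, f0: 0.1}
sweep: {c_min: -70.0, c_max: -40.0, c_step: 0.75, d_min: 0.1, d_max: 2.1, d_step: 0.05}
metrics: {n_segments: 30}
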