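# Signal response over the region #2 chaotic range under the weak signal.
name: region2_response
kind: response_sweep
params: {a: 0.2, b: 2.0, c: -56.0, d: -12.0, I: -99.0}
signal: {A: 0.01, f0: 0.1}
sweep: {d_min: -13.0, d_max: -11.9, d_step: 0.01}
metrics: {periods: 10000, lyapunov: forced, n_segments: 50}
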