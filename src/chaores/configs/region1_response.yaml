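# Signal response max_tau C(tau) and Lyapunov pairing over the region #1
# chaotic range under the weak signal A=1e-2, f0=0.1.
name: region1_response
kind: response_sweep
params: {a: 0.02, b: 0.2, c: -55.0, d: 0.85, I: 10.0}
signal: {A: 0.01, f0: 0.1}
sweep: {d_min: 0.88, d_max: 0.92, d_step: 0.0005}
metrics: {periods: 10000, lyapunov: forced, n_segments: 50}
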