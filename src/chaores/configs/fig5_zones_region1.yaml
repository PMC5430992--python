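# Resonant (f0, A) zones at the edge of chaos in region #1 (d = 0.896):
# cells with max_tau C(tau) > 0.5.  Pair with a `spectrum` run at the same
# parameters to compare zones against the signal-free power-spectrum peaks.
name: fig5_zones_region1
kind: resonance_map
params: {a: 0.02, b: 0.2, c: -55.0, d: 0.896, I: 10.0}
signal: {A: 0.0, f0: 0.1}
sweep:
  f0_values: [0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20]
  A_values: [0.001, 0.005, 0.01, 0.05, 0.1]
metrics: {periods: 2000, threshold: 0.5}
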