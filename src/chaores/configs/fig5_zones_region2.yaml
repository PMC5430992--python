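# Resonant (f0, A) zones at the edge of chaos in region #2 (d = -12.0).
name: fig5_zones_region2
kind: resonance_map
params: {a: 0.2, b: 2.0, c: -56.0, d: -12.0, I: -99.0}
signal: {A: 0.0, f0: 0.1}
sweep:
  f0_values: [0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20]
  A_values: [0.001, 0.005, 0.01, 0.05, 0.1]
metrics: {periods: 2000, threshold: 0.5}
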