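# Signal-free power spectrum of v(t) at the edge of chaos in region #2.
name: fig5_spectrum_region2
kind: spectrum
params: {a: 0.2, b: 2.0, c: -56.0, d: -12.0, I: -99.0}
signal: {A: 0.0, f0: 0.1}
metrics: {duration: 8192.0, sample_dt: 0.1}
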