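# Methods

## Model and scope

The pipeline analyses the planar Izhikevich hybrid neuron

    dv/dt = 0.04 v² + 5 v + 140 − u + I + I_ext(t),   I_ext(t) = A sin(2π f₀ t)
    du/dt = a (b v − u)
    reset: v ≥ 30  ⇒  (v, u) ← (c, u + d)

with time in ms and `f₀` in cycles/ms (`T₀ = 1/f₀` ms).  The model is
treated as an exact dynamical system: the questions asked of it —
bifurcation points, Lyapunov exponents, phase-locking statistics — are
properties of the flow itself, so the integration and event location are
pushed well below the scales on which any reported number depends.
Single neurons only; no synapses, noise terms, or non-sinusoidal inputs.

## Integration and event location

Between resets the flow is integrated with an adaptive Dormand–Prince
5(4) pair (relative/absolute tolerances 1e-10/1e-12, maximum step 5 ms),
implemented as a compiled kernel because the sweeps resolve of order 10⁶
threshold crossings.  A step that ends at or above v = 30 triggers
bisection on the step fraction — each probe is a full 5th-order step from
the stored step start — until the crossing is bracketed to ≈1e-11 mV,
giving spike times far below microsecond accuracy.  Only upward crossings
exist (from below threshold the flow reaches v = 30 with dv/dt > 0; at
the crossing dv/dt ≈ 330 in region #1).  If |dv/dt| at a located crossing
falls below 1e-8 the run aborts with a grazing error, since the saltation
matrix divides by it.  Correctness anchors: a fixed-step RK4 oracle at
1e-3 ms and an independent `scipy.solve_ivp` event integration reproduce
the kernel's spike times (tests).

Degenerate inputs are defined, not special-cased: a zero-length time span
returns the initial sample; a quiescent run returns an empty spike list;
`A = 0` makes the trajectory bitwise independent of `f₀`.

Unless configured otherwise, runs start from (v, u) = (c, b·c) and
discard a warm-up of 1000 ms or 100 spikes, whichever comes first.

## Lyapunov spectrum with saltation matrices

Perturbations follow the variational equation dΦ/dt = J(v) Φ with
J = [[0.08 v + 5, −1], [ab, −a]] (the forcing is state-independent and
drops out), integrated jointly with the state as a 6-dimensional system
so Φ is evaluated along the exact trajectory.  At each reset the
saltation matrix

    S = [[ v̇⁺/v̇⁻, 0 ], [ (u̇⁺ − u̇⁻)/v̇⁻, 1 ]]

is applied, with the pre-jump derivatives at (30, u⁻) and the post-jump
derivatives at (c, u⁻ + d), both at the crossing time (the same I_ext
enters both).  Its structural zero/one entries hold exactly by
construction, and det S = v̇⁺/v̇⁻.

Time is partitioned into segments that close at the 20th spike or after
1000 ms, whichever comes first.  Each segment's transition-matrix product
(flow pieces interleaved with saltation factors, starting from the
identity) contributes its two eigenvalue magnitudes, matched across
segments in descending order — the only stateless pairing rule, and the
one consistent with reporting λ₁ ≥ λ₂.  Complex pairs contribute their
common modulus √det.  The exponents are the time-averaged log magnitudes
over N segments; the default N = 50 (≈8 s of model time in region #1)
reproduces itself within 1e-3 when doubled in the chaotic regime (test).
2×2 products over ≤1000 ms stay far from overflow at the exponents
encountered (|λ| ≤ 0.1/ms), so no within-segment renormalization is
performed.

On a stable limit cycle λ₁ is the neutral direction along the orbit and
computes to 0 within ~1e-10; the acceptance property asserts |λ₁| < 5e-3.

## Section map and multipliers

The Poincaré section is Ψ(v = 30); section points are the pre-reset
recovery values u_i, giving the scalar return map ψ.  The derivative of
the l-fold return at a section point is

    μˡ = [ −u̇/v̇, 1 ] · Φ(t_l, t_0) · [0, 1]ᵀ

where Φ propagates a perturbation from the post-reset image of the
starting section point to the l-th return (saltation factors at interior
crossings), and the row vector projects the endpoint perturbation back
onto the section along the flow (a crossing-time shift δt = −δv/v̇
contributes u̇·δt to δu).  A perturbation confined to the section has
δv = 0, and S·(0, δu)ᵀ = (0, δu)ᵀ exactly, so the saltation factor at the
starting crossing is a no-op and is omitted.  The projection entry −u̇/v̇
is validated against a central finite difference of ψˡ (tolerance 1e-4,
tests); the transposed form −v̇/u̇ fails that oracle by orders of
magnitude.  |μ| < 1 is stable, μ = −1 a flip (period-doubling), μ = +1 a
tangent (saddle-node).

**Period detection.**  After settling (default 2000 returns beyond the
warm-up) the last 256 section values are scanned for the smallest
l ≤ 64 with |u_{i+l} − u_i| below 1e-6 of the tail range, floored at
1e-8·(1+|u|) so a machine-converged cycle is recognised.  Near a flip the
attractor converges critically slowly (contraction |μ| → 1), so
attractor settling alone misplaces the bifurcation: the decaying
period-2l component stays above any tolerance for thousands of returns on
one side and below it on the other.

**Newton continuation.**  Bifurcation points are therefore located on the
orbit itself: a fixed point of ψˡ is Newton-refined
(u ← u − (ψˡ(u) − u)/(μˡ − 1), derivative from the variational pathway),
which converges for mildly unstable orbits too, and the multiplier
crossing (μ = −1 or +1) is bisected in the swept parameter to 1e-5.
Newton's practical floor is the event-location noise in ψ (≈1e-9 in u);
residuals below 1e-6 are accepted since μ is insensitive at that scale.

In region #2 the attracting orbit's multiplier reaches the unit circle at
d ≈ −11.794: μ¹ → −1 and equivalently the 2-fold multiplier μ² → +1 at
the same parameter, with only unstable orbits (|μ| slightly > 1) and
sustained chaos (λ₁ > 0 over 3·10⁴ returns) beyond.  The tangent locator
therefore reports the +1 crossing of the 2l-fold return when the l-fold
multiplier does not itself cross +1 on the interval.  Chaos onset is
located by scanning λ₁ (step 5e-4 in d) for two consecutive values above
3e-3 — single positive values are unreliable amid the periodic windows
near the accumulation point — and bisecting the first crossing.

## Response statistics

The cycle histogram F(t̃) counts spike phases t_k mod T₀ in equal bins
over [0, T₀).  The default bin width is 1 ms (10 bins at f₀ = 0.1),
matching the integer-ms granularity in which the histogram is defined
(F(2), F(6), … for T₀ = 10); the bin count is configurable everywhere.
C(τ) is the Pearson-type normalized cross-covariance between F and the
signal evaluated at the bin centers shifted by τ, on a grid of 200 lags
in [0, T₀]; averages are uniform means over the bins.  Because the
reference is a pure sinusoid, C(τ) is itself sinusoidal in τ and
max_τ C(τ) equals the magnitude of the histogram's first Fourier
harmonic correlation; τ = 0 and τ = T₀ are the same lag and ties may
resolve to either.  C(τ) is undefined (an error, not a value) for a flat
histogram or a signal-free condition.

Forced sweeps run one continuous simulation per parameter value: warm-up,
then 10⁴ signal periods of spike collection (10⁵ ms; response values move
by < ~0.02 beyond that length).  Spike phases are folded in absolute
time, preserving the signal phase across the warm-up.

**Lyapunov pairing.**  The λ values paired with max_τ C(τ) are computed
*with the signal on* by default.  The weak forcing advances the chaotic
range: under A = 0.01 the region #1 flow has λ₁ > 0 from d ≈ 0.88, while
signal-free chaos only begins at d ≈ 0.894 — and the response is a
property of the forced system.  A flag (`lyapunov="signal-free"`)
computes the signal-free pairing instead.

**The periodic-regime response does not vanish in long runs.**  A weakly
forced periodic orbit here is generically unlocked (the 0.01-amplitude
tongues at the relevant high-order rotation numbers are far narrower than
the detuning): its spike phases drift through the signal cycle, and the
drift velocity is itself weakly modulated by the signal, so the phases'
stationary (sojourn) density acquires a small first harmonic aligned with
the signal.  max_τ C(τ) is scale-invariant, so as sampling fluctuations
average out this small but systematic component drives the correlation
up — to 0.3–0.95 depending on d — rather than to zero.  Trial ensembles
with randomized initial conditions and signal phases, and
segment-averaged C(τ) curves, converge to the same stationary response.
A near-zero periodic-regime floor is obtained only when spike-time
discretization noise (coarse fixed-step integration) or heavy counting
noise masks the drift coherence; with event-located integration the
pipeline reports the deterministic value.  Consequently the
periodic-regime floor computed here (~0.95 at 10⁴ periods) is a genuine
property of the exactly-integrated model under this protocol, and the
chaotic-peak values (~0.93 in region #1) sit above coarser estimates.
The peak *locations* (d ≈ 0.891 and d ≈ −12.3…−12.4) and the λ₁-binned
peak positions (≈0.02 and ≈0.04) are insensitive to these sampling
choices.

Power spectra of v(t) use dense-output resampling at 0.1 ms, a Hann
window, 8 Welch segments at 50% overlap, and prominence-based peak
picking (5% of the spectral maximum).  Resonance maps evaluate
max_τ C(τ) per (f₀, A) cell (2000 periods per cell by default) and mask
cells strictly above the 0.5 threshold.

## Synthetic spike trains

The generator draws an inhomogeneous point process with intensity
r₀(1 + m sin(2π f₀ t + φ)), m ∈ [0, 1], by thinning a homogeneous
envelope at r₀(1 + m) — exact for any bounded intensity and trivially
reproducible under a fixed seed.  It emulates the one feature the
response statistics measure, a controlled sinusoidal phase preference,
and deliberately nothing else: no refractoriness, no bursting, no
serial correlations.  Tests passing on these trains validate the
histogram/correlation machinery (law-of-large-numbers limits: m = 0.5
drives max C above 0.99, m = 0 stays at the counting-noise floor
≈ √(2/n_bins)), not any claim about the neuron's dynamics — those are
exercised against the simulator directly.  Deterministic phase combs
cover the exact small-sample cases.

## Problem sizes in tests and the acceptance script

The acceptance script sweeps region #1 at Δd = 5e-4 (81 points) and
region #2 at Δd = 0.01 (111 points), 10⁴ signal periods per forced point,
λ from 50 twenty-spike segments; bifurcation points use 3000 settling
returns and Newton bisection to 1e-5.  The test suite runs the same
sweeps at 5000 periods per point, where every asserted quantity is
already stable to well inside its tolerance.  The full pipeline is
deterministic end to end.

## Known limitations

* Only attracting orbits reached by forward simulation are analysed;
  there is no shooting/continuation for unstable branches beyond the
  local Newton refinement of the return map.
* Newton continuation requires the autonomous (signal-free) flow; forced
  bifurcation structure is characterised through λ and the response only.
* The λ₁-binned response peak is the argmax of a noisy plateau; it is
  reported at the resolution of the 0.001 bin width and moves by a bin
  or two under resampling.
* Near-grazing parameter sets (|dv/dt| < 1e-8 at a crossing) abort by
  design rather than regularising the saltation matrix.
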