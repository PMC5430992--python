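"""Cycle histogram, mutual correlation, spectra, resonance maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chaores import (
    PointProcessSpec,
    SignalParams,
    UndefinedVarianceError,
    cycle_histogram,
    deterministic_phase_train,
    lambda_binned_scatter,
    modulated_point_process,
    mutual_correlation,
    power_spectrum,
    response_sweep,
    resonance_map,
)
from chaores.response_metrics import CycleHistogram


def _hist_from_counts(counts, T0=10.0):
    counts = np.asarray(counts)
    return CycleHistogram(
        bin_edges=np.linspace(0.0, T0, len(counts) + 1),
        counts=counts,
        n_spikes=int(counts.sum()),
        T0=T0,
    )


def test_worked_histogram_example_exact():
    """T0 = 10 with spikes at 2, 6, 12, 16, 26 folds to phases 2,6,2,6,6,
    so the 1-ms-bin histogram has F(2) = 2 and F(6) = 3."""
    spikes = deterministic_phase_train(10.0, [[2.0, 6.0], [2.0, 6.0], [6.0]])
    assert np.array_equal(spikes, [2.0, 6.0, 12.0, 16.0, 26.0])
    hist = cycle_histogram(spikes, T0=10.0)
    assert len(hist.counts) == 10
    assert hist.counts[2] == 2
    assert hist.counts[6] == 3
    assert hist.counts.sum() == 5


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    st.lists(st.floats(0.0, 1e4, allow_nan=False), max_size=200),
    st.integers(2, 64),
)
def test_histogram_conserves_spike_count(times, n_bins):
    hist = cycle_histogram(times, T0=7.5, n_bins=n_bins)
    assert hist.counts.sum() == len(times)
    assert len(hist.counts) == n_bins
    assert hist.bin_edges[0] == 0.0 and hist.bin_edges[-1] == 7.5


def test_histogram_empty_and_aligned_spikes():
    assert np.all(cycle_histogram([], 10.0).counts == 0)
    hist = cycle_histogram([0.0, 10.0, 20.0, 30.0], 10.0)
    assert hist.counts[0] == 4 and hist.counts[1:].sum() == 0


def test_histogram_validates_inputs():
    with pytest.raises(ValueError):
        cycle_histogram([1.0], T0=0.0)
    with pytest.raises(ValueError):
        cycle_histogram([1.0], T0=10.0, n_bins=1)


def test_correlation_perfect_for_sinusoidal_histogram():
    sig = SignalParams(A=0.01, f0=0.1)
    hist = _hist_from_counts(
        100.0 + 50.0 * np.sin(2 * np.pi * 0.1 * (np.arange(100) + 0.5) * 0.1)
    )
    curve = mutual_correlation(hist, sig)
    assert curve.max_C == pytest.approx(1.0, abs=1e-9)
    # tau = 0 and tau = T0 are the same lag; either may win the tie
    assert min(curve.argmax_tau, 10.0 - curve.argmax_tau) <= 10.0 / 200


def test_correlation_antiphase_peaks_at_half_period():
    sig = SignalParams(A=0.01, f0=0.1)
    hist = _hist_from_counts(
        100.0 - 50.0 * np.sin(2 * np.pi * 0.1 * (np.arange(100) + 0.5) * 0.1)
    )
    curve = mutual_correlation(hist, sig)
    assert curve.values[0] == pytest.approx(-1.0, abs=1e-9)
    assert curve.max_C == pytest.approx(1.0, abs=1e-9)
    assert abs(curve.argmax_tau - 5.0) <= 10.0 / 200 + 1e-12


@settings(derandomize=True, deadline=None, max_examples=30)
@given(st.lists(st.integers(0, 1000), min_size=4, max_size=64))
def test_correlation_bounded_by_one(counts):
    if len(set(counts)) < 2:
        counts = list(counts)
        counts[0] += 1  # avoid the flat-histogram error path
    curve = mutual_correlation(_hist_from_counts(counts), SignalParams(0.01, 0.1))
    assert np.all(np.abs(curve.values) <= 1.0 + 1e-12)


def test_correlation_invariant_under_affine_rescaling():
    sig = SignalParams(A=0.01, f0=0.1)
    rng = np.random.default_rng(7)
    counts = rng.integers(1, 50, size=40).astype(float)
    c1 = mutual_correlation(_hist_from_counts(counts), sig)
    c2 = mutual_correlation(_hist_from_counts(3.0 * counts + 7.0), sig)
    assert np.allclose(c1.values, c2.values, atol=1e-12)


def test_correlation_undefined_variance_errors():
    flat = _hist_from_counts(np.full(20, 3.0))
    with pytest.raises(UndefinedVarianceError):
        mutual_correlation(flat, SignalParams(0.01, 0.1))
    bumpy = _hist_from_counts([1, 2, 3, 4])
    with pytest.raises(UndefinedVarianceError):
        mutual_correlation(bumpy, SignalParams(0.0, 0.1))


def test_phase_locked_point_process_drives_max_C_to_one():
    """Law-of-large-numbers oracle: a strongly modulated train correlates
    almost perfectly with the sinusoid."""
    spec = PointProcessSpec(
        base_rate=2.0, modulation_depth=0.5, f0=0.1, duration=1e5, seed=42
    )
    spikes = modulated_point_process(spec)
    hist = cycle_histogram(spikes, T0=10.0, n_bins=100)
    curve = mutual_correlation(hist, SignalParams(A=0.01, f0=0.1))
    assert curve.max_C > 0.99
    assert curve.argmax_tau < 0.5 or curve.argmax_tau > 9.5  # in phase


def test_unmodulated_point_process_gives_noise_floor():
    spec = PointProcessSpec(
        base_rate=2.0, modulation_depth=0.0, f0=0.1, duration=1e5, seed=43
    )
    spikes = modulated_point_process(spec)
    hist = cycle_histogram(spikes, T0=10.0, n_bins=100)
    curve = mutual_correlation(hist, SignalParams(A=0.01, f0=0.1))
    # pure counting noise: max_tau C is of order sqrt(2/n_bins) ~ 0.14
    assert curve.max_C < 0.3


def test_power_spectrum_finds_sinusoid_peaks():
    dt = 0.1
    t = np.arange(2**15) * dt
    x = np.sin(2 * np.pi * 0.05 * t)
    spec = power_spectrum(x, dt)
    assert len(spec.peak_frequencies) == 1
    assert spec.peak_frequencies[0] == pytest.approx(0.05, abs=2e-3)
    x2 = x + 0.5 * np.sin(2 * np.pi * 0.11 * t)
    spec2 = power_spectrum(x2, dt)
    assert len(spec2.peak_frequencies) == 2
    assert np.all(np.diff(spec2.frequencies) > 0)


def test_power_spectrum_rejects_short_series():
    with pytest.raises(ValueError):
        power_spectrum(np.ones(100), 0.1)


def test_response_sweep_small(region1, weak_signal):
    table = response_sweep(
        region1, [0.85, 0.90], weak_signal, periods=300, n_segments=10
    )
    assert list(table["d"]) == [0.85, 0.90]
    assert table["max_C"].between(-1, 1).all()
    assert table["n_spikes"].gt(0).all()
    assert table["lambda1"].notna().all()
    assert (table["error"] == "").all()


def test_response_sweep_signal_free_pairing(region1, weak_signal):
    table = response_sweep(
        region1, [0.85], weak_signal, periods=200, n_segments=10,
        lyapunov="signal-free",
    )
    # signal-free lambda_1 on the stable cycle is ~0
    assert abs(table["lambda1"].iloc[0]) < 5e-3


def test_response_sweep_requires_forcing(region1):
    with pytest.raises(ValueError):
        response_sweep(region1, [0.85], SignalParams(0.0, 0.1))


def test_lambda_binned_scatter_known_argmax():
    import pandas as pd

    sweep = pd.DataFrame(
        {
            "lambda1": [0.0005, 0.0012, 0.0014, 0.0031, 0.0033],
            "max_C": [0.1, 0.5, 0.7, 0.2, 0.4],
        }
    )
    binned = lambda_binned_scatter(sweep, window=0.001)
    assert len(binned) == 3
    best = binned.loc[binned["mean_max_C"].idxmax()]
    assert best["lambda1_bin"] == pytest.approx(0.0015)
    assert best["mean_max_C"] == pytest.approx(0.6)
    single = lambda_binned_scatter(sweep.iloc[:1], window=0.001)
    assert len(single) == 1
    assert single["mean_max_C"].iloc[0] == pytest.approx(0.1)


def test_resonance_map_smoke(region1):
    rmap = resonance_map(
        region1.with_d(0.896), [0.08, 0.1], [0.005, 0.05], periods=100
    )
    assert rmap.max_C.shape == (2, 2)
    assert np.isfinite(rmap.max_C).all()
    assert rmap.errors == {}
    assert np.array_equal(rmap.resonant_mask, rmap.max_C > 0.5)
    df = rmap.to_frame()
    assert set(df.columns) == {"f0", "A", "max_C", "resonant"}
    with pytest.raises(ValueError):
        resonance_map(region1, [], [0.01])
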