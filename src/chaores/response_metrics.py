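"""Signal-response statistics for chaotic resonance.

The response of the spike train to the weak sinusoid I_ext(t) =
A sin(2 pi f0 t) is measured on the cycle histogram F(t~): firing counts of
t_k mod T0 (T0 = 1/f0) over one signal period.  The normalized mutual
correlation

    C(tau) = C_IF(tau) / sqrt(C_II C_FF)

is the Pearson-type cross-covariance between F and the lag-shifted signal
evaluated at the bin centers, and max_tau C(tau) over 0 <= tau <= T0 is the
scalar response index.  A resonance map evaluates that index over an
(f0, A) grid; the power spectrum of v(t) in the signal-free condition
identifies the intrinsic periodic components the resonant zones align with.

Default bin width is 1 ms (the cycle-histogram counts firing per
integer-ms phase, e.g. F(2), F(6) for T0 = 10), i.e. T0/1ms bins per
period; both the bin count and the lag grid are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .hybrid_model import (
    DEFAULT_ATOL,
    DEFAULT_MAX_STEP,
    DEFAULT_RTOL,
    NO_SIGNAL,
    NeuronParams,
    SignalParams,
    SimulationError,
    State,
    run_spike_train,
    simulate,
    warmup,
)
from .variational_lyapunov import lyapunov_spectrum

__all__ = [
    "CycleHistogram",
    "CorrelationCurve",
    "PowerSpectrum",
    "ResonanceMap",
    "UndefinedVarianceError",
    "cycle_histogram",
    "mutual_correlation",
    "measure_response",
    "response_sweep",
    "lambda_binned_scatter",
    "power_spectrum",
    "spectrum_of_model",
    "resonance_map",
]

#: default histogram bin width (ms)
BIN_WIDTH_MS = 1.0
#: default number of lags in [0, T0]
N_LAGS = 200
#: default forced-run duration in signal periods
DEFAULT_PERIODS = 10_000


class UndefinedVarianceError(ValueError):
    """C(tau) is undefined: C_FF = 0 (flat histogram) or C_II = 0 (A = 0)."""


@dataclass(frozen=True)
class CycleHistogram:
    """Firing counts of t_k mod T0 over one signal period."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_spikes: int
    T0: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts})


@dataclass(frozen=True)
class CorrelationCurve:
    lags: np.ndarray
    values: np.ndarray
    max_C: float
    argmax_tau: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.lags, "C": self.values})


@dataclass(frozen=True)
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray
    peak_frequencies: np.ndarray
    peak_powers: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.frequencies, "power": self.power})


@dataclass
class ResonanceMap:
    f0_values: np.ndarray
    A_values: np.ndarray
    max_C: np.ndarray  # shape (len(A_values), len(f0_values))
    threshold: float = 0.5
    errors: dict = field(default_factory=dict)

    @property
    def resonant_mask(self) -> np.ndarray:
        return self.max_C > self.threshold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, A in enumerate(self.A_values):
            for j, f0 in enumerate(self.f0_values):
                rows.append(
                    {
                        "f0": f0,
                        "A": A,
                        "max_C": self.max_C[i, j],
                        "resonant": bool(self.max_C[i, j] > self.threshold),
                    }
                )
        return pd.DataFrame(rows)


def default_n_bins(T0: float) -> int:
    """Bins per period at the default 1 ms bin width (at least 2)."""
    return max(2, int(round(T0 / BIN_WIDTH_MS)))


def cycle_histogram(spike_times, T0: float, n_bins: int | None = None) -> CycleHistogram:
    """Histogram of t_k mod T0 with equal bins covering [0, T0).

    An empty spike list yields an all-zero histogram.
    """
    if not T0 > 0:
        raise ValueError("T0 must be positive")
    if n_bins is None:
        n_bins = default_n_bins(T0)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    spike_times = np.asarray(spike_times, dtype=float)
    edges = np.linspace(0.0, T0, n_bins + 1)
    counts, _ = np.histogram(np.mod(spike_times, T0), bins=edges)
    return CycleHistogram(
        bin_edges=edges, counts=counts, n_spikes=int(len(spike_times)), T0=T0
    )


def mutual_correlation(
    hist: CycleHistogram,
    signal: SignalParams,
    n_lags: int = N_LAGS,
) -> CorrelationCurve:
    """C(tau) for tau on an even grid over [0, T0], plus its maximum.

    The signal is evaluated at the histogram bin centers shifted by tau;
    averages are uniform means over the bins of one period.
    """
    F = hist.counts.astype(float)
    Fc = F - F.mean()
    c_ff = float(np.mean(Fc * Fc))
    if c_ff == 0.0:
        raise UndefinedVarianceError("flat cycle histogram: C_FF = 0")
    if signal.A == 0.0:
        raise UndefinedVarianceError("signal-free condition: C_II = 0")
    taus = np.linspace(0.0, hist.T0, n_lags + 1)
    centers = hist.bin_centers
    sig = signal.value(centers[None, :] + taus[:, None])
    sig_c = sig - sig.mean(axis=1, keepdims=True)
    c_ii = np.mean(sig_c * sig_c, axis=1)
    c_if = sig_c @ Fc / len(F)
    values = c_if / np.sqrt(c_ii * c_ff)
    imax = int(np.argmax(values))
    return CorrelationCurve(
        lags=taus,
        values=values,
        max_C=float(values[imax]),
        argmax_tau=float(taus[imax]),
    )


def measure_response(
    params: NeuronParams,
    signal: SignalParams,
    periods: int = DEFAULT_PERIODS,
    n_bins: int | None = None,
    n_lags: int = N_LAGS,
    warmup_t: float = 1000.0,
    warmup_spikes: int = 100,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
):
    """Forced run -> cycle histogram -> (max_C, argmax_tau, n_spikes).

    One continuous simulation: warm-up (discarded) followed by `periods`
    signal periods of spike collection; spike phases are taken modulo T0
    in absolute time so the signal phase is preserved across the warm-up.
    """
    if signal.A <= 0:
        raise ValueError("measure_response requires a forced signal (A > 0)")
    state = warmup(
        params, signal, t_max=warmup_t, max_spikes=warmup_spikes,
        rtol=rtol, atol=atol, max_step=max_step,
    )
    t_end = state.t + periods * signal.T0
    spike_t, _su, _ = run_spike_train(
        params, signal, init=state, t_max=t_end,
        max_spikes=int(2.0 * periods * signal.T0) + 256,
        rtol=rtol, atol=atol, max_step=max_step,
    )
    hist = cycle_histogram(spike_t, signal.T0, n_bins=n_bins)
    curve = mutual_correlation(hist, signal, n_lags=n_lags)
    return curve.max_C, curve.argmax_tau, hist.n_spikes


def response_sweep(
    template: NeuronParams,
    d_values,
    signal: SignalParams,
    periods: int = DEFAULT_PERIODS,
    n_bins: int | None = None,
    n_lags: int = N_LAGS,
    lyapunov: str = "forced",
    n_segments: int = 50,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
    progress=None,
) -> pd.DataFrame:
    """Per-d signal response paired with the Lyapunov spectrum.

    `lyapunov` selects the pairing condition: "forced" evaluates the
    exponents with the signal on (the default: the forced exponents
    reproduce the chaotic-range boundaries the response actually sees),
    "signal-free" with A = 0, None skips them.  Failures are quarantined
    per point.
    """
    if signal.A <= 0:
        raise ValueError("response_sweep requires a forced signal (A > 0)")
    if lyapunov not in ("forced", "signal-free", None):
        raise ValueError("lyapunov must be 'forced', 'signal-free', or None")
    d_values = np.asarray(d_values, dtype=float)
    if len(d_values) == 0:
        raise ValueError("empty d range")
    rows = []
    for d in d_values:
        p = template.with_d(float(d))
        row = {
            "d": float(d),
            "max_C": np.nan,
            "argmax_tau": np.nan,
            "lambda1": np.nan,
            "lambda2": np.nan,
            "n_spikes": 0,
            "error": "",
        }
        try:
            max_c, tau, n_sp = measure_response(
                p, signal, periods=periods, n_bins=n_bins, n_lags=n_lags,
                rtol=rtol, atol=atol, max_step=max_step,
            )
            row["max_C"] = max_c
            row["argmax_tau"] = tau
            row["n_spikes"] = n_sp
            if lyapunov is not None:
                sig_l = signal if lyapunov == "forced" else NO_SIGNAL
                spec = lyapunov_spectrum(
                    p, sig_l, n_segments=n_segments,
                    rtol=rtol, atol=atol, max_step=max_step,
                )
                row["lambda1"] = spec.lambda1
                row["lambda2"] = spec.lambda2
        except (SimulationError, UndefinedVarianceError) as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if progress is not None:
            progress(row)
    return pd.DataFrame(rows)


def lambda_binned_scatter(
    sweep: pd.DataFrame, window: float = 0.001
) -> pd.DataFrame:
    """Mean max_C per lambda_1 bin of fixed width `window`.

    Bins are [k*window, (k+1)*window); empty bins are skipped.  The row
    with the largest mean is the resonance peak of the scatter plot.
    """
    if len(sweep) == 0:
        raise ValueError("empty sweep")
    ok = sweep.dropna(subset=["lambda1", "max_C"])
    if len(ok) == 0:
        raise ValueError("no valid (lambda1, max_C) pairs")
    k = np.floor(ok["lambda1"].to_numpy() / window).astype(int)
    df = pd.DataFrame(
        {"bin": k, "lambda1_bin": (k + 0.5) * window, "max_C": ok["max_C"].to_numpy()}
    )
    out = (
        df.groupby("bin")
        .agg(lambda1_bin=("lambda1_bin", "first"), mean_max_C=("max_C", "mean"),
             n_points=("max_C", "size"))
        .reset_index(drop=True)
        .sort_values("lambda1_bin")
        .reset_index(drop=True)
    )
    return out


def power_spectrum(
    v,
    sample_dt: float,
    n_welch_segments: int = 8,
    overlap: float = 0.5,
    prominence_rel: float = 0.05,
) -> PowerSpectrum:
    """Welch periodogram of a uniformly sampled series with peak detection.

    Hann window, `n_welch_segments` segments at the given overlap; peaks
    are local maxima with prominence at least `prominence_rel` times the
    spectral maximum.
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 2**10:
        raise ValueError("series too short for a Welch estimate")
    nperseg = int(len(v) / (n_welch_segments * (1 - overlap) + overlap))
    nperseg = max(256, nperseg)
    freqs, power = _sig.welch(
        v, fs=1.0 / sample_dt, window="hann", nperseg=nperseg,
        noverlap=int(overlap * nperseg), detrend="constant",
    )
    idx, _props = _sig.find_peaks(power, prominence=prominence_rel * power.max())
    return PowerSpectrum(
        frequencies=freqs,
        power=power,
        peak_frequencies=freqs[idx],
        peak_powers=power[idx],
    )


def spectrum_of_model(
    params: NeuronParams,
    duration: float = 8192.0,
    sample_dt: float = 0.1,
    signal: SignalParams = NO_SIGNAL,
    warmup_t: float = 1000.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    **spectrum_kwargs,
) -> PowerSpectrum:
    """Power spectrum of v(t), by default in the signal-free condition."""
    state = warmup(params, signal, t_max=warmup_t, rtol=rtol, atol=atol)
    traj = simulate(
        params, signal, t_span=(state.t, state.t + duration),
        init=State(state.t, state.v, state.u), sample_dt=sample_dt,
        rtol=rtol, atol=atol,
    )
    return power_spectrum(traj.v, sample_dt, **spectrum_kwargs)


def resonance_map(
    params: NeuronParams,
    f0_values,
    A_values,
    threshold: float = 0.5,
    periods: int = 2000,
    n_bins: int | None = None,
    n_lags: int = N_LAGS,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
    progress=None,
) -> ResonanceMap:
    """max_tau C(tau) over an (f0, A) grid; mask where it exceeds threshold.

    Per-cell failures are flagged (NaN in the grid, message in `errors`).
    """
    f0_values = np.asarray(f0_values, dtype=float)
    A_values = np.asarray(A_values, dtype=float)
    if len(f0_values) == 0 or len(A_values) == 0:
        raise ValueError("empty (f0, A) grid")
    grid = np.full((len(A_values), len(f0_values)), np.nan)
    errors: dict = {}
    for i, A in enumerate(A_values):
        for j, f0 in enumerate(f0_values):
            sig = SignalParams(A=float(A), f0=float(f0))
            try:
                max_c, _tau, _n = measure_response(
                    params, sig, periods=periods, n_bins=n_bins, n_lags=n_lags,
                    rtol=rtol, atol=atol, max_step=max_step,
                )
                grid[i, j] = max_c
            except (SimulationError, UndefinedVarianceError) as exc:
                errors[(float(A), float(f0))] = f"{type(exc).__name__}: {exc}"
            if progress is not None:
                progress(A, f0, grid[i, j])
    return ResonanceMap(
        f0_values=f0_values, A_values=A_values, max_C=grid,
        threshold=threshold, errors=errors,
    )
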