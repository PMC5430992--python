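"""Spike-train generators with known phase-locking structure.

The response statistics (cycle histogram, lag-maximized mutual correlation)
are testable without the neuron simulator against trains whose locking to a
sinusoid is controlled exactly: an inhomogeneous point process with
intensity r0 (1 + m sin(2 pi f0 t + phi)) drawn by thinning, and fully
deterministic phase combs.  Spike-time output uses the same schema as the
simulator's spike export, so every metric consumes either interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PointProcessSpec",
    "modulated_point_process",
    "deterministic_phase_train",
    "spikes_to_frame",
]


@dataclass(frozen=True)
class PointProcessSpec:
    """Sinusoidally rate-modulated point process.

    base_rate r0 in spikes/ms; modulation depth m in [0, 1] (m = 0 is a
    homogeneous process); f0 in cycles/ms; phase in radians; duration in
    ms; seed for reproducibility.
    """

    base_rate: float
    modulation_depth: float
    f0: float
    duration: float
    phase: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError(
                "modulation depth must lie in [0, 1] so the intensity stays "
                "non-negative"
            )
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    def intensity(self, t):
        """Target intensity r0 (1 + m sin(2 pi f0 t + phase))."""
        t = np.asarray(t, dtype=float)
        return self.base_rate * (
            1.0 + self.modulation_depth * np.sin(2.0 * np.pi * self.f0 * t + self.phase)
        )


def modulated_point_process(
    spec: PointProcessSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw spike times by thinning a homogeneous envelope.

    Candidates are Poisson at the envelope rate r0 (1 + m) and kept with
    probability intensity(t) / envelope; exact for any bounded intensity.
    Reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r_max = spec.base_rate * (1.0 + spec.modulation_depth)
    n_cand = rng.poisson(r_max * spec.duration)
    t_cand = np.sort(rng.uniform(0.0, spec.duration, size=n_cand))
    accept = rng.uniform(0.0, 1.0, size=n_cand) < spec.intensity(t_cand) / r_max
    return t_cand[accept]


def deterministic_phase_train(T0: float, phases, n_cycles: int | None = None) -> np.ndarray:
    """Deterministic comb: emit the given phases once per cycle.

    `phases` is either a flat sequence (each phase repeated every cycle for
    `n_cycles` cycles) or a sequence of per-cycle phase sequences (ragged
    combs; `n_cycles` is then taken from its length).  All phases must lie
    in [0, T0).
    """
    if not T0 > 0:
        raise ValueError("T0 must be positive")
    per_cycle: list[np.ndarray]
    if len(phases) > 0 and np.ndim(phases[0]) > 0:
        per_cycle = [np.asarray(p, dtype=float) for p in phases]
        if n_cycles is not None and n_cycles != len(per_cycle):
            raise ValueError("n_cycles disagrees with the per-cycle phase list")
    else:
        if n_cycles is None:
            raise ValueError("n_cycles is required with a flat phase list")
        base = np.asarray(phases, dtype=float)
        per_cycle = [base] * n_cycles
    out = []
    for k, p in enumerate(per_cycle):
        if np.any((p < 0) | (p >= T0)):
            raise ValueError("phases must lie in [0, T0)")
        out.append(k * T0 + np.sort(p))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def spikes_to_frame(spike_times) -> pd.DataFrame:
    """Spike times in the simulator's spike-export schema."""
    spike_times = np.asarray(spike_times, dtype=float)
    return pd.DataFrame(
        {
            "t_spike": spike_times,
            "u_pre": np.full_like(spike_times, np.nan),
            "u_post": np.full_like(spike_times, np.nan),
        }
    )
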