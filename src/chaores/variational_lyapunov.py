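"""Lyapunov spectrum of the hybrid flow via saltation matrices.

Perturbations are propagated by the variational equation dPhi/dt = J Phi
along the smooth flow and corrected at every reset by the saltation matrix

    S = [[ v'(+)/v'(-)            , 0 ],
         [ (u'(+) - u'(-))/v'(-)  , 1 ]]

with the derivatives evaluated just before (v = 30, u-) and just after
(v = c, u- + d) the jump, at the crossing time.  Time is partitioned into
segments that close after 20 spikes or 1000 ms, whichever comes first; the
two exponents are the time-averaged logs of the per-segment eigenvalue
magnitudes of the accumulated transition-matrix products, matched across
segments in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as _k
from .hybrid_model import (
    CROSSING_TOL,
    DEFAULT_ATOL,
    DEFAULT_MAX_STEP,
    DEFAULT_RTOL,
    NO_SIGNAL,
    GrazingError,
    NeuronParams,
    SignalParams,
    State,
    V_THRESHOLD,
    _raise_for_status,
    vector_field,
    warmup,
)

__all__ = [
    "TransitionMatrix",
    "SaltationMatrix",
    "SegmentRecord",
    "LyapunovSpectrum",
    "jacobian",
    "saltation_matrix",
    "segment_transition_matrix",
    "lyapunov_spectrum",
    "spectrum_from_segments",
]

#: spikes per Lyapunov segment
SPIKES_PER_SEGMENT = 20
#: hard time cap on one segment (ms)
SEGMENT_T_MAX = 1000.0
#: default number of segments
DEFAULT_N_SEGMENTS = 50

GRAZING_GUARD = _k.GRAZING_GUARD


@dataclass(frozen=True)
class TransitionMatrix:
    """State-transition matrix Phi(t_to, t_from) of the variational flow."""

    entries: np.ndarray
    t_from: float
    t_to: float


@dataclass(frozen=True)
class SaltationMatrix:
    """Jump correction inserted into the variational flow at a reset."""

    entries: np.ndarray
    t_spike: float


@dataclass(frozen=True)
class SegmentRecord:
    """One Lyapunov segment: transition-matrix product and its eigenvalue
    magnitudes (sorted descending)."""

    t_start: float
    t_end: float
    matrix: np.ndarray
    eigen_magnitudes: tuple[float, float]
    n_spikes: int


@dataclass(frozen=True)
class LyapunovSpectrum:
    """Sorted Lyapunov exponents (1/ms) with bookkeeping."""

    lambda1: float
    lambda2: float
    n_segments: int
    total_time: float
    segments: tuple[SegmentRecord, ...] = ()

    def segments_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start": [s.t_start for s in self.segments],
                "t_end": [s.t_end for s in self.segments],
                "n_spikes": [s.n_spikes for s in self.segments],
                "l1_mag": [s.eigen_magnitudes[0] for s in self.segments],
                "l2_mag": [s.eigen_magnitudes[1] for s in self.segments],
            }
        )


def jacobian(state: State, params: NeuronParams) -> np.ndarray:
    """Jacobian of the smooth flow.

    The forcing term is state-independent, so it does not appear here.
    """
    return np.array(
        [
            [0.08 * state.v + 5.0, -1.0],
            [params.a * params.b, -params.a],
        ]
    )


def saltation_matrix(
    pre_state: State,
    params: NeuronParams,
    signal: SignalParams = NO_SIGNAL,
    tol: float = CROSSING_TOL,
) -> SaltationMatrix:
    """Saltation matrix at a located crossing of v = 30.

    `pre_state` must sit on the threshold (within `tol`); both derivative
    pairs are evaluated at the crossing time so the same I_ext enters each.
    """
    if abs(pre_state.v - V_THRESHOLD) > tol:
        raise ValueError(
            f"pre-reset state has v={pre_state.v}, not on the section v=30"
        )
    vd_m, ud_m = vector_field(pre_state, params, signal)
    if abs(vd_m) < GRAZING_GUARD:
        raise GrazingError(
            f"grazing crossing at t={pre_state.t}: |dv/dt|={abs(vd_m):.2e}"
        )
    post = State(t=pre_state.t, v=params.c, u=pre_state.u + params.d)
    vd_p, ud_p = vector_field(post, params, signal)
    entries = np.array(
        [
            [vd_p / vd_m, 0.0],
            [(ud_p - ud_m) / vd_m, 1.0],
        ]
    )
    return SaltationMatrix(entries=entries, t_spike=pre_state.t)


def _eigen_magnitudes(m: np.ndarray) -> tuple[float, float]:
    tr = m[0, 0] + m[1, 1]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    disc = 0.25 * tr * tr - det
    if disc >= 0.0:
        rt = np.sqrt(disc)
        e1, e2 = abs(0.5 * tr + rt), abs(0.5 * tr - rt)
    else:
        # complex pair: both moduli equal sqrt(det)
        e1 = e2 = float(np.sqrt(abs(det)))
    return (e1, e2) if e1 >= e2 else (e2, e1)


def segment_transition_matrix(
    params: NeuronParams,
    init: State,
    t_end: float,
    signal: SignalParams = NO_SIGNAL,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> SegmentRecord:
    """Transition matrix over [init.t, t_end] along the trajectory from
    `init`, saltation factors included at every reset inside the interval.

    A zero-length interval returns the identity.
    """
    if t_end < init.t:
        raise ValueError("t_end must not precede init.t")
    if t_end == init.t:
        return SegmentRecord(init.t, t_end, np.eye(2), (1.0, 1.0), 0)
    (seg_ts, seg_te, seg_ns, _l1, _l2, seg_phi, _tf, _vf, _uf, status) = (
        _k.run_lyapunov_segments(
            params.a,
            params.b,
            params.c,
            params.d,
            params.I,
            signal.A,
            signal.f0,
            init.t,
            init.v,
            init.u,
            1,
            np.iinfo(np.int64).max,
            t_end - init.t,
            rtol,
            atol,
            max_step,
        )
    )
    _raise_for_status(status, "segment_transition_matrix")
    m = seg_phi[0]
    return SegmentRecord(
        t_start=float(seg_ts[0]),
        t_end=float(seg_te[0]),
        matrix=m,
        eigen_magnitudes=_eigen_magnitudes(m),
        n_spikes=int(seg_ns[0]),
    )


def spectrum_from_segments(
    matrices, t_start: float, t_end: float
) -> tuple[float, float]:
    """Lyapunov exponents from per-segment transition matrices.

    lambda_j = (1 / (T^N - T^0)) * sum_k log |l_j^k| with the eigenvalue
    magnitudes of each segment product sorted descending.  Exposed
    separately so the accumulation rule can be checked against closed
    forms (e.g. matrix exponentials of a constant Jacobian).
    """
    total = t_end - t_start
    if total <= 0:
        raise ValueError("segment sequence must span positive time")
    s1 = s2 = 0.0
    for m in matrices:
        e1, e2 = _eigen_magnitudes(np.asarray(m, dtype=float))
        if e2 <= 0.0:
            raise ArithmeticError("singular segment transition matrix")
        s1 += np.log(e1)
        s2 += np.log(e2)
    return s1 / total, s2 / total


def lyapunov_spectrum(
    params: NeuronParams,
    signal: SignalParams = NO_SIGNAL,
    n_segments: int = DEFAULT_N_SEGMENTS,
    init: State | None = None,
    do_warmup: bool = True,
    spikes_per_segment: int = SPIKES_PER_SEGMENT,
    segment_t_max: float = SEGMENT_T_MAX,
    keep_segments: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> LyapunovSpectrum:
    """Two-exponent Lyapunov spectrum of the hybrid flow.

    After an optional warm-up, integrates `n_segments` segments (each
    closing at the `spikes_per_segment`-th spike or after `segment_t_max`
    ms) and averages the per-segment log eigenvalue magnitudes.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    state = init
    if do_warmup:
        state = warmup(
            params, signal, init=init, t0=0.0 if init is None else init.t,
            rtol=rtol, atol=atol, max_step=max_step,
        )
    elif state is None:
        raise ValueError("init is required when do_warmup=False")
    (seg_ts, seg_te, seg_ns, l1, l2, seg_phi, _tf, _vf, _uf, status) = (
        _k.run_lyapunov_segments(
            params.a,
            params.b,
            params.c,
            params.d,
            params.I,
            signal.A,
            signal.f0,
            state.t,
            state.v,
            state.u,
            n_segments,
            spikes_per_segment,
            segment_t_max,
            rtol,
            atol,
            max_step,
        )
    )
    if len(seg_ts) < n_segments:
        _raise_for_status(status, "lyapunov_spectrum")
    if np.any(l2 <= 0.0):
        raise ArithmeticError("singular segment transition matrix")
    total = float(seg_te[-1] - seg_ts[0])
    lam1 = float(np.sum(np.log(l1)) / total)
    lam2 = float(np.sum(np.log(l2)) / total)
    segments: tuple[SegmentRecord, ...] = ()
    if keep_segments:
        segments = tuple(
            SegmentRecord(
                t_start=float(seg_ts[k]),
                t_end=float(seg_te[k]),
                matrix=seg_phi[k],
                eigen_magnitudes=(float(l1[k]), float(l2[k])),
                n_spikes=int(seg_ns[k]),
            )
            for k in range(len(seg_ts))
        )
    return LyapunovSpectrum(
        lambda1=lam1,
        lambda2=lam2,
        n_segments=int(len(seg_ts)),
        total_time=total,
        segments=segments,
    )
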