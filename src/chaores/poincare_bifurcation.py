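"""Section-map analysis on the Poincare section Psi(v = 30).

Every upward threshold crossing contributes its pre-reset recovery value
u_i; the induced map u_{i+1} = psi(u_i) reduces the hybrid flow to a scalar
return map.  The derivative of the l-fold return map at a periodic point
(the characteristic multiplier mu^l) is obtained by propagating the
variational system over one orbit return -- saltation factors included --
and projecting the endpoint perturbation back onto the section along the
flow:

    mu^l = [-du/dt / dv/dt, 1] . Phi(t_l, t_0) . [0, 1]^T

with the derivatives evaluated at the closing section point.  |mu| < 1 is
stable; mu = -1 marks a period-doubling and mu = +1 a tangent (saddle-node)
bifurcation.  Bifurcation points are located by bisecting attractor
predicates (detected period, periodicity, sign of lambda_1) over the swept
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as _k
from .hybrid_model import (
    DEFAULT_ATOL,
    DEFAULT_MAX_STEP,
    DEFAULT_RTOL,
    NO_SIGNAL,
    GrazingError,
    NeuronParams,
    SignalParams,
    SimulationError,
    State,
    Trajectory,
    _raise_for_status,
    run_spike_train,
    warmup,
)
from .variational_lyapunov import lyapunov_spectrum

__all__ = [
    "SectionSequence",
    "PeriodicOrbit",
    "MultiplierResult",
    "BifurcationPoint",
    "BifurcationDiagram",
    "section_sequence",
    "detect_period",
    "section_map",
    "find_periodic_orbit",
    "characteristic_multiplier",
    "sweep_bifurcation",
    "locate_period_doubling",
    "locate_tangent",
    "locate_attractor_boundary",
    "locate_multiplier_crossing",
    "refine_orbit_newton",
    "locate_chaos_onset",
    "lyapunov_map",
]

#: maximum period tried by the detector
L_MAX = 64
#: tail window examined by the detector
DETECT_WINDOW = 256
#: relative (to the tail range) tolerance of the detector
DETECT_TOL_REL = 1e-6
#: classification half-width for mu = -1 / mu = +1
EPS_BIFURCATION = 1e-3


@dataclass(frozen=True)
class SectionSequence:
    """Ordered pre-reset u values on the section with their crossing times."""

    u_values: np.ndarray
    times: np.ndarray

    def __len__(self) -> int:
        return len(self.u_values)


@dataclass(frozen=True)
class PeriodicOrbit:
    """A detected attracting periodic orbit of the section map."""

    period_l: int
    u_cycle: np.ndarray
    cycle_time: float
    t0: float
    u0: float


@dataclass(frozen=True)
class MultiplierResult:
    mu: float
    classification: str  # stable | period_doubling | tangent | unstable


@dataclass(frozen=True)
class BifurcationPoint:
    type: str  # period_doubling | tangent | chaos_onset
    parameter: float
    bracket: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "type": self.type,
            "parameter": self.parameter,
            "bracket": list(self.bracket),
        }


@dataclass
class BifurcationDiagram:
    """Sweep result: per-parameter summary, section tails, located points."""

    table: pd.DataFrame
    tails: dict[float, np.ndarray]
    points: list[BifurcationPoint] = field(default_factory=list)

    def tails_to_frame(self) -> pd.DataFrame:
        rows = [(d, u) for d, tail in self.tails.items() for u in tail]
        return pd.DataFrame(rows, columns=["d", "u_i"])


def section_sequence(trajectory: Trajectory) -> SectionSequence:
    """Extract the section sequence from a simulated trajectory.

    Empty when the run produced no spikes (quiescent regime).
    """
    return SectionSequence(
        u_values=np.asarray(trajectory.spike_u_pre, dtype=float),
        times=np.asarray(trajectory.spike_times, dtype=float),
    )


def detect_period(
    seq,
    tol: float | None = None,
    l_max: int = L_MAX,
    window: int = DETECT_WINDOW,
) -> int | None:
    """Smallest l <= l_max with |u_{i+l} - u_i| < tol over the tail window.

    Returns None when no such l exists (aperiodic).  The default tolerance
    is DETECT_TOL_REL times the tail range, floored at 1e-8(1 + max|u|) so
    a fully converged cycle (machine-noise tail) is still recognised.
    """
    u = np.asarray(seq.u_values if isinstance(seq, SectionSequence) else seq, dtype=float)
    if len(u) < 4 * l_max:
        raise ValueError(
            f"need at least {4 * l_max} section values, got {len(u)}"
        )
    tail = u[-window:]
    if tol is None:
        rng = float(tail.max() - tail.min())
        tol = max(DETECT_TOL_REL * rng, 1e-8 * (1.0 + float(np.abs(tail).max())))
    for l in range(1, l_max + 1):
        if np.all(np.abs(tail[l:] - tail[:-l]) < tol):
            return l
    return None


def section_map(
    params: NeuronParams,
    u0: float,
    n_returns: int = 1,
    t0: float = 0.0,
    signal: SignalParams = NO_SIGNAL,
    t_max: float = 1e7,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> float:
    """psi^n(u0): simulate n section returns from the point (v=30, u0).

    Used as the brute-force oracle for the variational multiplier (finite
    differences of this map) and by Newton orbit refinement.
    """
    init = State(t=t0, v=params.c, u=u0 + params.d)  # post-reset image
    spike_t, spike_u, _state = run_spike_train(
        params,
        signal,
        init=init,
        t_max=t0 + t_max,
        max_spikes=n_returns,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if len(spike_u) < n_returns:
        raise SimulationError(
            f"only {len(spike_u)} returns within t_max={t_max}"
        )
    return float(spike_u[-1])


def find_periodic_orbit(
    params: NeuronParams,
    signal: SignalParams = NO_SIGNAL,
    settle: int = 2000,
    window: int = DETECT_WINDOW,
    tol: float | None = None,
    l_max: int = L_MAX,
    init: State | None = None,
    settle_t_max: float = 1e6,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> PeriodicOrbit | None:
    """Settle onto the attractor and return its periodic orbit, or None.

    Runs `settle` section returns after the standard warm-up, detects the
    period over the tail window, and anchors the orbit at the last crossing.
    None signals an aperiodic (or quiescent) attractor.
    """
    state = warmup(params, signal, init=init, rtol=rtol, atol=atol, max_step=max_step)
    spike_t, spike_u, _ = run_spike_train(
        params,
        signal,
        init=state,
        t_max=state.t + settle_t_max,
        max_spikes=settle,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if len(spike_u) < 4 * l_max:
        return None
    l = detect_period(spike_u, tol=tol, l_max=l_max, window=window)
    if l is None:
        return None
    cycle = spike_u[-l:]
    cycle_time = float(spike_t[-1] - spike_t[-1 - l]) if len(spike_t) > l else 0.0
    return PeriodicOrbit(
        period_l=l,
        u_cycle=np.asarray(cycle, dtype=float),
        cycle_time=cycle_time,
        t0=float(spike_t[-1]),
        u0=float(spike_u[-1]),
    )


def _classify(mu: float, eps_b: float) -> str:
    if abs(mu + 1.0) < eps_b:
        return "period_doubling"
    if abs(mu - 1.0) < eps_b:
        return "tangent"
    return "stable" if abs(mu) < 1.0 else "unstable"


def characteristic_multiplier(
    params: NeuronParams,
    orbit: PeriodicOrbit,
    signal: SignalParams = NO_SIGNAL,
    eps_b: float = EPS_BIFURCATION,
    t_max: float = 1e7,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> MultiplierResult:
    """Characteristic multiplier mu^l of a periodic section orbit.

    Propagates the variational system over one l-fold return from the
    orbit anchor and projects onto the section; classification thresholds
    at |mu -+ 1| < eps_b.
    """
    phi, t_l, _u_pre, vdot, udot, status = _k.run_phi_returns(
        params.a,
        params.b,
        params.c,
        params.d,
        params.I,
        signal.A,
        signal.f0,
        orbit.t0,
        orbit.u0,
        orbit.period_l,
        t_max,
        rtol,
        atol,
        max_step,
    )
    if status == _k.STATUS_NO_RETURN:
        raise SimulationError("orbit did not return to the section in time")
    _raise_for_status(status, "characteristic_multiplier")
    if abs(vdot) < _k.GRAZING_GUARD:
        raise GrazingError("grazing section return")
    if abs(udot) < 1e-8:
        raise SimulationError("du/dt vanished at the section point")
    mu = float(-(udot / vdot) * phi[0, 1] + phi[1, 1])
    return MultiplierResult(mu=mu, classification=_classify(mu, eps_b))


def _attractor_summary(
    params, signal, settle, window, tol, l_max, compute_mu, rtol, atol, max_step
):
    """(period or None, mu or nan, tail, anchor orbit or None)."""
    orbit = find_periodic_orbit(
        params, signal, settle=settle, window=window, tol=tol, l_max=l_max,
        rtol=rtol, atol=atol, max_step=max_step,
    )
    mu = float("nan")
    if orbit is not None and compute_mu:
        mu = characteristic_multiplier(
            params, orbit, signal, rtol=rtol, atol=atol, max_step=max_step
        ).mu
    return orbit, mu


def sweep_bifurcation(
    template: NeuronParams,
    d_values,
    signal: SignalParams = NO_SIGNAL,
    settle: int = 2000,
    window: int = DETECT_WINDOW,
    tail_keep: int = 64,
    l_max: int = L_MAX,
    compute_lyapunov: bool = True,
    n_segments: int = 50,
    compute_mu: bool = True,
    locate_points: bool = True,
    tol_d: float = 1e-4,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
    progress=None,
) -> BifurcationDiagram:
    """Bifurcation diagram over a d sweep.

    Per parameter value: warm-up, settle on the attractor, store the last
    `tail_keep` section values, detect the period, and (when periodic)
    compute the multiplier; optionally the Lyapunov spectrum.  Transitions
    between consecutive grid points are refined by bisection.  Per-point
    failures are recorded in the table and the sweep continues.
    """
    d_values = np.asarray(d_values, dtype=float)
    if len(d_values) == 0:
        raise ValueError("empty d range")
    rows = []
    tails: dict[float, np.ndarray] = {}
    for d in d_values:
        p = template.with_d(float(d))
        row = {
            "d": float(d),
            "period": np.nan,
            "mu": np.nan,
            "lambda1": np.nan,
            "lambda2": np.nan,
            "error": "",
        }
        try:
            state = warmup(p, signal, rtol=rtol, atol=atol, max_step=max_step)
            spike_t, spike_u, _ = run_spike_train(
                p, signal, init=state, t_max=state.t + 1e6, max_spikes=settle,
                rtol=rtol, atol=atol, max_step=max_step,
            )
            tails[float(d)] = spike_u[-tail_keep:]
            if len(spike_u) >= 4 * l_max:
                l = detect_period(spike_u, l_max=l_max, window=window)
                if l is not None:
                    row["period"] = l
                    if compute_mu:
                        orbit = PeriodicOrbit(
                            period_l=l,
                            u_cycle=spike_u[-l:],
                            cycle_time=float(spike_t[-1] - spike_t[-1 - l]),
                            t0=float(spike_t[-1]),
                            u0=float(spike_u[-1]),
                        )
                        row["mu"] = characteristic_multiplier(
                            p, orbit, signal, rtol=rtol, atol=atol,
                            max_step=max_step,
                        ).mu
            if compute_lyapunov:
                spec = lyapunov_spectrum(
                    p, signal, n_segments=n_segments, rtol=rtol, atol=atol,
                    max_step=max_step,
                )
                row["lambda1"] = spec.lambda1
                row["lambda2"] = spec.lambda2
        except SimulationError as exc:  # quarantine, keep sweeping
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if progress is not None:
            progress(row)
    table = pd.DataFrame(rows)
    points: list[BifurcationPoint] = []
    if locate_points and len(d_values) > 1:
        points = _locate_sweep_points(
            template, d_values, table, signal, settle, window, l_max,
            tol_d, n_segments if compute_lyapunov else 0,
            rtol, atol, max_step,
        )
    return BifurcationDiagram(table=table, tails=tails, points=points)


def _bisect(pred, lo, hi, tol):
    """Bisect pred (True at lo, False at hi) to |hi-lo| < tol.

    The bracket may be ascending or descending.
    """
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if pred(mid):
            lo = mid
        else:
            hi = mid
    return lo, hi


def refine_orbit_newton(
    params: NeuronParams,
    u0: float,
    l: int,
    signal: SignalParams = NO_SIGNAL,
    tol: float = 5e-9,
    max_iter: int = 40,
    t_max: float = 1e7,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> tuple[float, float]:
    """Newton-refine a fixed point of psi^l from the guess u0.

    Returns (u_star, mu) where mu is the multiplier at the refined point.
    Works for mildly unstable orbits too (the variational derivative is
    evaluated along the actual trajectory), which is what makes unbiased
    multiplier-crossing bisection possible: near a bifurcation the
    attractor converges too slowly to settle on, but Newton still lands
    on the orbit.  Signal-free flows only (the map must be autonomous).
    """
    if signal.A != 0.0:
        raise ValueError("Newton refinement requires the autonomous flow (A=0)")
    u = float(u0)
    best = (np.inf, u, np.nan)  # (|residual|, u, mu)
    for _ in range(max_iter):
        phi, _t_l, u_l, vdot, udot, status = _k.run_phi_returns(
            params.a, params.b, params.c, params.d, params.I,
            signal.A, signal.f0, 0.0, u, l, t_max, rtol, atol, max_step,
        )
        if status == _k.STATUS_NO_RETURN:
            raise SimulationError("orbit lost during Newton refinement")
        _raise_for_status(status, "refine_orbit_newton")
        mu = float(-(udot / vdot) * phi[0, 1] + phi[1, 1])
        f = u_l - u
        if abs(f) < best[0]:
            best = (abs(f), u, mu)
        if abs(f) < tol:
            return u, mu
        denom = mu - 1.0
        if abs(denom) < 1e-10:
            raise SimulationError("Newton singular: multiplier at +1")
        step = -f / denom
        if abs(step) > 1.0:
            step = np.sign(step) * 1.0
        u += step
    # event-location noise (~1e-9 in u) can keep the residual just above a
    # tight tolerance; accept the best iterate when it is already far below
    # any scale the multiplier is sensitive to
    if best[0] < max(100.0 * tol, 1e-6):
        return best[1], best[2]
    raise SimulationError(f"Newton did not converge from u0={u0}")


def locate_multiplier_crossing(
    template: NeuronParams,
    d_from: float,
    d_to: float,
    l: int,
    u_guess: float,
    target: float = -1.0,
    signal: SignalParams = NO_SIGNAL,
    tol_d: float = 1e-5,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> BifurcationPoint:
    """Bisect the d at which mu^l of the period-l orbit crosses `target`.

    The orbit is continued in d by Newton refinement from the previous
    point, so the crossing is located without settling on the attractor
    (which suffers critical slowing near the bifurcation).  `u_guess` must
    lie near the period-l orbit at d_from.
    """
    state = {"u": float(u_guess)}

    def mu_at(d: float) -> float:
        u_star, mu = refine_orbit_newton(
            template.with_d(d), state["u"], l, signal,
            rtol=rtol, atol=atol, max_step=max_step,
        )
        state["u"] = u_star
        return mu

    mu_from = mu_at(d_from)
    mu_to = mu_at(d_to)
    s_from = np.sign(mu_from - target)
    if s_from == np.sign(mu_to - target):
        raise ValueError(
            f"mu^{l} - ({target}) does not change sign on "
            f"[{d_from}, {d_to}]: {mu_from:.6f} vs {mu_to:.6f}"
        )
    lo, hi = _bisect(
        lambda d: np.sign(mu_at(d) - target) == s_from, d_from, d_to, tol_d
    )
    kind = "period_doubling" if target == -1.0 else "tangent"
    lo_s, hi_s = sorted((lo, hi))
    return BifurcationPoint(kind, 0.5 * (lo_s + hi_s), (lo_s, hi_s))


def _locate_sweep_points(
    template, d_values, table, signal, settle, window, l_max, tol_d,
    n_segments, rtol, atol, max_step,
):
    points: list[BifurcationPoint] = []
    periods = table["period"].to_numpy()
    lams = table["lambda1"].to_numpy()
    asc = d_values[-1] >= d_values[0]
    for i in range(len(d_values) - 1):
        d0, d1 = float(d_values[i]), float(d_values[i + 1])
        p0, p1 = periods[i], periods[i + 1]
        if np.isnan(p0) and np.isnan(p1):
            pass
        elif not np.isnan(p0) and not np.isnan(p1) and p1 == 2 * p0:
            pt = locate_period_doubling(
                template, d0, d1, l_ref=int(p0), signal=signal,
                settle=settle, window=window, tol_d=tol_d,
                rtol=rtol, atol=atol, max_step=max_step,
            )
            points.append(pt)
        elif np.isnan(p0) != np.isnan(p1):
            pt = locate_attractor_boundary(
                template, d0, d1, signal=signal, settle=settle,
                window=window, l_max=l_max, tol_d=tol_d,
                rtol=rtol, atol=atol, max_step=max_step,
            )
            points.append(pt)
        if n_segments and not np.isnan(lams[i]) and not np.isnan(lams[i + 1]):
            thr = 3e-3
            if (lams[i] > thr) != (lams[i + 1] > thr):
                lo, hi = sorted((d0, d1))
                points.append(
                    BifurcationPoint("chaos_onset", 0.5 * (lo + hi), (lo, hi))
                )
    _ = asc
    return points


def locate_period_doubling(
    template: NeuronParams,
    d_stable: float,
    d_doubled: float,
    l_ref: int | None = None,
    signal: SignalParams = NO_SIGNAL,
    settle: int = 3000,
    window: int = DETECT_WINDOW,
    tol_d: float = 1e-5,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> BifurcationPoint:
    """Bisect the parameter at which mu^l of the attractor crosses -1.

    `d_stable` must carry the stable period-l_ref attractor and
    `d_doubled` the doubled (or aperiodic) regime.  The orbit is continued
    across the interval by Newton refinement, so the location is free of
    the critical-slowing bias that afflicts attractor-settling detection
    near the bifurcation.
    """
    orbit = find_periodic_orbit(
        template.with_d(d_stable), signal, settle=settle, window=window,
        rtol=rtol, atol=atol, max_step=max_step,
    )
    if orbit is None:
        raise ValueError(f"no periodic attractor at d={d_stable}")
    if l_ref is None:
        l_ref = orbit.period_l
    return locate_multiplier_crossing(
        template, d_stable, d_doubled, l=l_ref, u_guess=orbit.u0,
        target=-1.0, signal=signal, tol_d=tol_d,
        rtol=rtol, atol=atol, max_step=max_step,
    )


def locate_tangent(
    template: NeuronParams,
    d_periodic: float,
    d_aperiodic: float,
    l: int | None = None,
    signal: SignalParams = NO_SIGNAL,
    settle: int = 3000,
    window: int = DETECT_WINDOW,
    tol_d: float = 1e-5,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> BifurcationPoint:
    """Bisect the parameter at which a return-map multiplier crosses +1.

    The attracting orbit at `d_periodic` fixes the reference period; the
    crossing is searched for the l-fold return first and, when mu^l does
    not cross +1 on the interval, for the 2l-fold return (at the boundary
    of a period-doubled window mu^l reaches -1 and mu^{2l} reaches +1 at
    the same parameter).
    """
    orbit = find_periodic_orbit(
        template.with_d(d_periodic), signal, settle=settle, window=window,
        rtol=rtol, atol=atol, max_step=max_step,
    )
    if orbit is None:
        raise ValueError(f"no periodic attractor at d={d_periodic}")
    if l is None:
        l = orbit.period_l
    try:
        return locate_multiplier_crossing(
            template, d_periodic, d_aperiodic, l=l, u_guess=orbit.u0,
            target=1.0, signal=signal, tol_d=tol_d,
            rtol=rtol, atol=atol, max_step=max_step,
        )
    except ValueError:
        return locate_multiplier_crossing(
            template, d_periodic, d_aperiodic, l=2 * l, u_guess=orbit.u0,
            target=1.0, signal=signal, tol_d=tol_d,
            rtol=rtol, atol=atol, max_step=max_step,
        )


def locate_attractor_boundary(
    template: NeuronParams,
    d_aperiodic: float,
    d_periodic: float,
    signal: SignalParams = NO_SIGNAL,
    settle: int = 6000,
    window: int = DETECT_WINDOW,
    l_max: int = L_MAX,
    tol_d: float = 1e-4,
    eps_b: float = 5e-3,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> BifurcationPoint:
    """Bisect the boundary where the periodic attractor ceases to exist.

    The point is classified as tangent when the multiplier of the l-fold
    (or 2l-fold) return approaches +1 on the periodic side.
    """

    def is_periodic(d: float) -> bool:
        orbit = find_periodic_orbit(
            template.with_d(d), signal, settle=settle, window=window,
            l_max=l_max, rtol=rtol, atol=atol, max_step=max_step,
        )
        return orbit is not None

    # orient so pred is True on the periodic side
    if is_periodic(d_periodic) and not is_periodic(d_aperiodic):
        lo, hi = _bisect(is_periodic, d_periodic, d_aperiodic, tol_d)
    else:
        raise ValueError(
            "expected a periodic attractor at d_periodic and not at d_aperiodic"
        )
    d_edge_periodic = lo
    kind = "tangent"
    try:
        orbit = find_periodic_orbit(
            template.with_d(d_edge_periodic), signal, settle=settle,
            window=window, l_max=l_max, rtol=rtol, atol=atol, max_step=max_step,
        )
        if orbit is not None:
            mu_l = characteristic_multiplier(
                template.with_d(d_edge_periodic), orbit, signal,
                rtol=rtol, atol=atol, max_step=max_step,
            ).mu
            mu_2l = mu_l * mu_l  # multiplier of the doubled return
            if not (abs(mu_2l - 1.0) < eps_b or abs(mu_l - 1.0) < eps_b):
                kind = "attractor_boundary"
    except SimulationError:
        kind = "attractor_boundary"
    lo_s, hi_s = sorted((lo, hi))
    return BifurcationPoint(kind, 0.5 * (lo_s + hi_s), (lo_s, hi_s))


def locate_chaos_onset(
    template: NeuronParams,
    d_lo: float,
    d_hi: float,
    signal: SignalParams = NO_SIGNAL,
    scan_step: float = 5e-4,
    lam_thresh: float = 3e-3,
    n_segments: int = 50,
    tol_d: float = 2.5e-4,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> BifurcationPoint:
    """Smallest d in [d_lo, d_hi] at which lambda_1 is persistently positive.

    Scans upward with `scan_step`, requires two consecutive grid points
    above `lam_thresh` (chaotic windows near the accumulation point make a
    single positive value unreliable), then bisects the first crossing.
    """

    def lam1(d: float) -> float:
        return lyapunov_spectrum(
            template.with_d(d), signal, n_segments=n_segments,
            rtol=rtol, atol=atol, max_step=max_step,
        ).lambda1

    grid = np.arange(d_lo, d_hi + 0.5 * scan_step, scan_step)
    vals = [lam1(float(d)) for d in grid]
    first = None
    for i in range(len(grid) - 1):
        if vals[i] > lam_thresh and vals[i + 1] > lam_thresh:
            first = i
            break
    if first is None:
        raise SimulationError(
            f"lambda_1 never persistently exceeded {lam_thresh} in "
            f"[{d_lo}, {d_hi}]"
        )
    if first == 0:
        lo, hi = float(grid[0]) - scan_step, float(grid[0])
    else:
        lo, hi = _bisect(
            lambda d: lam1(d) <= lam_thresh, float(grid[first - 1]), float(grid[first]), tol_d
        )
    lo_s, hi_s = sorted((lo, hi))
    return BifurcationPoint("chaos_onset", 0.5 * (lo_s + hi_s), (lo_s, hi_s))


def lyapunov_map(
    template: NeuronParams,
    c_values,
    d_values,
    signal: SignalParams = NO_SIGNAL,
    n_segments: int = 50,
    n_jobs: int = 1,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> pd.DataFrame:
    """lambda_1 over a (c, d) grid, long format.

    Failed cells are flagged in the `error` column instead of aborting.
    """
    from dataclasses import replace

    from joblib import Parallel, delayed

    c_values = np.asarray(c_values, dtype=float)
    d_values = np.asarray(d_values, dtype=float)
    if len(c_values) == 0 or len(d_values) == 0:
        raise ValueError("empty (c, d) grid")

    def cell(cv: float, dv: float) -> dict:
        out = {"c": cv, "d": dv, "lambda1": np.nan, "lambda2": np.nan, "error": ""}
        try:
            p = replace(template, c=cv, d=dv)
            spec = lyapunov_spectrum(
                p, signal, n_segments=n_segments, rtol=rtol, atol=atol,
                max_step=max_step,
            )
            out["lambda1"] = spec.lambda1
            out["lambda2"] = spec.lambda2
        except (SimulationError, ArithmeticError, ValueError) as exc:
            out["error"] = f"{type(exc).__name__}: {exc}"
        return out

    rows = Parallel(n_jobs=n_jobs)(
        delayed(cell)(float(cv), float(dv)) for cv in c_values for dv in d_values
    )
    return pd.DataFrame(rows)
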