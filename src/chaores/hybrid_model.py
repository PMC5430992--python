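"""Event-driven simulation of the (optionally forced) Izhikevich neuron.

The model is the planar hybrid system

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I + A sin(2 pi f0 t)
    du/dt = a (b v - u)

with the after-spike reset  v <- c, u <- u + d  applied whenever the
membrane potential reaches the threshold v = 30 mV from below.  Between
resets the flow is smooth; the integrator locates each threshold crossing
by root-finding inside the accepted step, so spike times are resolved far
below the step size.

Units: time in ms, v in mV; f0 is in cycles/ms so the signal period is
T0 = 1/f0 ms.  a, b, c, d, I are the standard dimensionless model constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as _k

__all__ = [
    "NeuronParams",
    "SignalParams",
    "State",
    "SpikeEvent",
    "Trajectory",
    "SimulationError",
    "GrazingError",
    "DivergenceError",
    "EventLocationError",
    "V_THRESHOLD",
    "vector_field",
    "apply_reset",
    "simulate",
    "warmup",
    "REGION1",
    "REGION2",
]

V_THRESHOLD = 30.0

#: default crossing tolerance used when validating pre-reset states
CROSSING_TOL = 1e-6

DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12
DEFAULT_MAX_STEP = 5.0


class SimulationError(RuntimeError):
    """Base class for integration failures."""


class GrazingError(SimulationError):
    """|dv/dt| at a located crossing fell below the grazing guard (1e-8).

    The saltation matrix divides by the pre-reset dv/dt, so a grazing
    crossing would make the variational propagation blow up.
    """


class DivergenceError(SimulationError):
    """The flow produced a non-finite state."""


class EventLocationError(SimulationError):
    """Event location / step control failed to converge."""


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the Izhikevich model.

    a : recovery rate (1/ms); b : recovery sensitivity; c : reset potential
    (mV, must lie below the 30 mV threshold); d : after-spike recovery
    increment; I : constant input current.
    """

    a: float
    b: float
    c: float
    d: float
    I: float

    def __post_init__(self) -> None:
        if not self.c < V_THRESHOLD:
            raise ValueError(
                f"reset potential c={self.c} must lie below the spike "
                f"threshold {V_THRESHOLD}"
            )

    def with_d(self, d: float) -> "NeuronParams":
        """Copy of the parameter set with a different recovery increment."""
        return replace(self, d=d)


@dataclass(frozen=True)
class SignalParams:
    """Sinusoidal forcing I_ext(t) = A sin(2 pi f0 t).

    A = 0 encodes the signal-free condition; f0 is in cycles per ms.
    """

    A: float = 0.0
    f0: float = 0.1

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("signal amplitude A must be >= 0")
        if not self.f0 > 0:
            raise ValueError("signal frequency f0 must be > 0")

    @property
    def T0(self) -> float:
        """Signal period in ms."""
        return 1.0 / self.f0

    def value(self, t):
        """I_ext evaluated at time(s) t."""
        return self.A * np.sin(2.0 * np.pi * self.f0 * np.asarray(t, dtype=float))


NO_SIGNAL = SignalParams(A=0.0, f0=0.1)

#: parameter template of the period-doubling region (region #1)
REGION1 = NeuronParams(a=0.02, b=0.2, c=-55.0, d=0.85, I=10.0)
#: parameter template of the tangent/intermittency region (region #2)
REGION2 = NeuronParams(a=0.2, b=2.0, c=-56.0, d=-12.0, I=-99.0)


@dataclass(frozen=True)
class State:
    """A point (t, v, u) on the trajectory."""

    t: float
    v: float
    u: float


@dataclass(frozen=True)
class SpikeEvent:
    """One located threshold crossing with its pre- and post-reset states."""

    t_spike: float
    pre_state: State
    post_state: State


@dataclass
class Trajectory:
    """Dense samples plus the ordered spike events of one simulation."""

    t: np.ndarray
    v: np.ndarray
    u: np.ndarray
    spike_times: np.ndarray
    spike_u_pre: np.ndarray
    params: NeuronParams
    signal: SignalParams = field(default=NO_SIGNAL)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def samples(self) -> list[State]:
        return [State(*row) for row in zip(self.t, self.v, self.u)]

    @property
    def spikes(self) -> list[SpikeEvent]:
        p = self.params
        return [
            SpikeEvent(
                t_spike=ts,
                pre_state=State(ts, V_THRESHOLD, up),
                post_state=State(ts, p.c, up + p.d),
            )
            for ts, up in zip(self.spike_times, self.spike_u_pre)
        ]

    @property
    def final_state(self) -> State:
        return State(float(self.t[-1]), float(self.v[-1]), float(self.u[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "v": self.v, "u": self.u})

    def spikes_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_spike": self.spike_times,
                "u_pre": self.spike_u_pre,
                "u_post": self.spike_u_pre + self.params.d,
            }
        )

    def export_csv(self, samples_path=None, spikes_path=None) -> None:
        if samples_path is not None:
            self.to_frame().to_csv(samples_path, index=False)
        if spikes_path is not None:
            self.spikes_to_frame().to_csv(spikes_path, index=False)


def vector_field(state: State, params: NeuronParams, signal: SignalParams = NO_SIGNAL):
    """Right-hand side (dv/dt, du/dt) of the forced flow at `state`."""
    dv = (
        0.04 * state.v * state.v
        + 5.0 * state.v
        + 140.0
        - state.u
        + params.I
        + signal.A * np.sin(2.0 * np.pi * signal.f0 * state.t)
    )
    du = params.a * (params.b * state.v - state.u)
    return dv, du


def apply_reset(
    pre_state: State, params: NeuronParams, tol: float = CROSSING_TOL
) -> State:
    """After-spike reset v <- c, u <- u + d.

    Rejects states with v below threshold (beyond `tol`): that indicates
    the event location failed upstream.
    """
    if pre_state.v < V_THRESHOLD - tol:
        raise EventLocationError(
            f"reset requested at v={pre_state.v}, more than tol={tol} below "
            f"the threshold {V_THRESHOLD}"
        )
    return State(t=pre_state.t, v=params.c, u=pre_state.u + params.d)


def _raise_for_status(status: int, context: str) -> None:
    if status == _k.STATUS_GRAZING:
        raise GrazingError(f"grazing threshold crossing during {context}")
    if status == _k.STATUS_NONFINITE:
        raise DivergenceError(f"non-finite state during {context}")
    if status in (_k.STATUS_UNDERFLOW, _k.STATUS_MAXSTEPS):
        raise EventLocationError(f"integrator failed to converge during {context}")


def default_init(params: NeuronParams, t0: float = 0.0) -> State:
    """Default initial condition (v, u) = (c, b c)."""
    return State(t=t0, v=params.c, u=params.b * params.c)


def simulate(
    params: NeuronParams,
    signal: SignalParams = NO_SIGNAL,
    t_span: tuple[float, float] = (0.0, 1000.0),
    init: State | None = None,
    sample_dt: float = 0.1,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
    max_spikes: int | None = None,
) -> Trajectory:
    """Integrate the hybrid flow over `t_span` with event-located resets.

    Returns a Trajectory with uniform samples every `sample_dt` ms and the
    ordered spike events.  Deterministic for identical inputs and settings.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not np.isfinite(t0) or not np.isfinite(t1) or t1 < t0:
        raise ValueError(f"invalid t_span {t_span}")
    if init is None:
        init = default_init(params, t0)
    if init.v >= V_THRESHOLD:
        raise ValueError("initial state must lie below the spike threshold")
    if t1 == t0:
        return Trajectory(
            t=np.array([t0]),
            v=np.array([init.v]),
            u=np.array([init.u]),
            spike_times=np.empty(0),
            spike_u_pre=np.empty(0),
            params=params,
            signal=signal,
        )
    if max_spikes is None:
        # generous cap: observed rates stay well below 1 spike/ms
        max_spikes = int(2.0 * (t1 - t0)) + 64
    (
        samp_t,
        samp_v,
        samp_u,
        spike_t,
        spike_u,
        _ns,
        _tf,
        _vf,
        _uf,
        status,
    ) = _k.run_dense(
        params.a,
        params.b,
        params.c,
        params.d,
        params.I,
        signal.A,
        signal.f0,
        t0,
        init.v,
        init.u,
        t1,
        sample_dt,
        max_spikes,
        rtol,
        atol,
        max_step,
    )
    _raise_for_status(status, "simulate")
    if status == _k.STATUS_SPIKE:
        raise EventLocationError(
            f"spike budget of {max_spikes} exhausted before t={t1}"
        )
    return Trajectory(
        t=samp_t,
        v=samp_v,
        u=samp_u,
        spike_times=spike_t,
        spike_u_pre=spike_u,
        params=params,
        signal=signal,
    )


def run_spike_train(
    params: NeuronParams,
    signal: SignalParams = NO_SIGNAL,
    t0: float = 0.0,
    init: State | None = None,
    t_max: float = np.inf,
    max_spikes: int = 1000,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
):
    """Spike-oriented simulation: stop after `max_spikes` spikes or `t_max`.

    Returns (spike_times, spike_u_pre, final State).  Cheaper than
    `simulate` because no dense samples are stored.
    """
    if init is None:
        init = default_init(params, t0)
    t_end = t_max if np.isfinite(t_max) else t0 + 1e12
    spike_t, spike_u, _ns, tf, vf, uf, status = _k.run_spikes(
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
        t_end,
        max_spikes,
        rtol,
        atol,
        max_step,
    )
    _raise_for_status(status, "run_spike_train")
    return spike_t, spike_u, State(tf, vf, uf)


def warmup(
    params: NeuronParams,
    signal: SignalParams = NO_SIGNAL,
    init: State | None = None,
    t0: float = 0.0,
    t_max: float = 1000.0,
    max_spikes: int = 100,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> State:
    """Discard the initial transient: `t_max` ms or `max_spikes` spikes,
    whichever comes first.  Returns the state at the end of the transient
    (post-reset if it ended on a spike)."""
    _st, _su, state = run_spike_train(
        params,
        signal,
        t0=t0,
        init=init,
        t_max=t0 + t_max,
        max_spikes=max_spikes,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    return state
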