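"""Low-level numba kernels: adaptive Dormand-Prince 5(4) integration of the
Izhikevich flow with event-located threshold crossings, the augmented
state+variational system, and per-segment transition-matrix products.

Status codes returned by the kernels:
  0  reached the requested end time
  1  located an upward crossing of v = 30 (state left at the pre-reset point)
  2  step size underflow
  3  step budget exhausted
  4  grazing crossing (|dv/dt| below the guard at the located event)
  5  non-finite state encountered
  6  requested number of returns not reached within the time cap
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi

V_THRESHOLD = 30.0
GRAZING_GUARD = 1e-8

STATUS_END = 0
STATUS_SPIKE = 1
STATUS_UNDERFLOW = 2
STATUS_MAXSTEPS = 3
STATUS_GRAZING = 4
STATUS_NONFINITE = 5
STATUS_NO_RETURN = 6

# Dormand-Prince 5(4) tableau (the classic RK45 pair with FSAL).
_C2 = 1.0 / 5.0
_C3 = 3.0 / 10.0
_C4 = 4.0 / 5.0
_C5 = 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31 = 3.0 / 40.0
_A32 = 9.0 / 40.0
_A41 = 44.0 / 45.0
_A42 = -56.0 / 15.0
_A43 = 32.0 / 9.0
_A51 = 19372.0 / 6561.0
_A52 = -25360.0 / 2187.0
_A53 = 64448.0 / 6561.0
_A54 = -212.0 / 729.0
_A61 = 9017.0 / 3168.0
_A62 = -355.0 / 33.0
_A63 = 46732.0 / 5247.0
_A64 = 49.0 / 176.0
_A65 = -5103.0 / 18656.0
_B1 = 35.0 / 384.0
_B3 = 500.0 / 1113.0
_B4 = 125.0 / 192.0
_B5 = -2187.0 / 6784.0
_B6 = 11.0 / 84.0
_E1 = 71.0 / 57600.0
_E3 = -71.0 / 16695.0
_E4 = 71.0 / 1920.0
_E5 = -17253.0 / 339200.0
_E6 = 22.0 / 525.0
_E7 = -1.0 / 40.0

_H_MIN = 1e-12
_MAX_STEPS = 200_000_000


@njit(cache=True, inline="always")
def _rhs(t, y, out, n, a, b, I, A, f0):
    v = y[0]
    u = y[1]
    out[0] = 0.04 * v * v + 5.0 * v + 140.0 - u + I + A * math.sin(TWO_PI * f0 * t)
    out[1] = a * (b * v - u)
    if n == 6:
        # variational flow: dPhi/dt = J Phi with J = [[0.08 v + 5, -1], [a b, -a]]
        jvv = 0.08 * v + 5.0
        out[2] = jvv * y[2] - y[4]
        out[3] = jvv * y[3] - y[5]
        out[4] = a * b * y[2] - a * y[4]
        out[5] = a * b * y[3] - a * y[5]


@njit(cache=True, inline="always")
def _vdot(t, v, u, I, A, f0):
    return 0.04 * v * v + 5.0 * v + 140.0 - u + I + A * math.sin(TWO_PI * f0 * t)


@njit(cache=True, inline="always")
def _udot(v, u, a, b):
    return a * (b * v - u)


@njit(cache=True)
def _try_step(t, y, h, n, k, ynew, a, b, I, A, f0, rtol, atol):
    """One DP5(4) step of size h from (t, y); k[0] must hold f(t, y).

    Writes the 5th-order result into ynew and f(t+h, ynew) into k[6];
    returns the scaled error norm (accept when <= 1).
    """
    for i in range(n):
        ynew[i] = y[i] + h * (_A21 * k[0, i])
    _rhs(t + _C2 * h, ynew, k[1], n, a, b, I, A, f0)
    for i in range(n):
        ynew[i] = y[i] + h * (_A31 * k[0, i] + _A32 * k[1, i])
    _rhs(t + _C3 * h, ynew, k[2], n, a, b, I, A, f0)
    for i in range(n):
        ynew[i] = y[i] + h * (_A41 * k[0, i] + _A42 * k[1, i] + _A43 * k[2, i])
    _rhs(t + _C4 * h, ynew, k[3], n, a, b, I, A, f0)
    for i in range(n):
        ynew[i] = y[i] + h * (
            _A51 * k[0, i] + _A52 * k[1, i] + _A53 * k[2, i] + _A54 * k[3, i]
        )
    _rhs(t + _C5 * h, ynew, k[4], n, a, b, I, A, f0)
    for i in range(n):
        ynew[i] = y[i] + h * (
            _A61 * k[0, i]
            + _A62 * k[1, i]
            + _A63 * k[2, i]
            + _A64 * k[3, i]
            + _A65 * k[4, i]
        )
    _rhs(t + h, ynew, k[5], n, a, b, I, A, f0)
    for i in range(n):
        ynew[i] = y[i] + h * (
            _B1 * k[0, i] + _B3 * k[2, i] + _B4 * k[3, i] + _B5 * k[4, i] + _B6 * k[5, i]
        )
    _rhs(t + h, ynew, k[6], n, a, b, I, A, f0)
    err = 0.0
    for i in range(n):
        e = h * (
            _E1 * k[0, i]
            + _E3 * k[2, i]
            + _E4 * k[3, i]
            + _E5 * k[4, i]
            + _E6 * k[5, i]
            + _E7 * k[6, i]
        )
        sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
        err += (e / sc) * (e / sc)
    return math.sqrt(err / n)


@njit(cache=True, inline="always")
def _hermite(theta, h, y0, f0v, y1, f1v):
    t2 = theta * theta
    t3 = t2 * theta
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + theta
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    return h00 * y0 + h10 * h * f0v + h01 * y1 + h11 * h * f1v


@njit(cache=True)
def _advance(
    y,
    t,
    t_end,
    h,
    n,
    a,
    b,
    I,
    A,
    f0,
    rtol,
    atol,
    max_step,
    k,
    ynew,
    ybis,
    sample_dt,
    t0_samp,
    samp_state,
    samp_t,
    samp_v,
    samp_u,
):
    """Advance the flow until t_end or the first upward crossing of v = 30.

    y is modified in place. Returns (t, h, status). When sample_dt > 0,
    cubic-Hermite samples on the uniform grid t0_samp + i*sample_dt are
    appended to samp_t/v/u; samp_state[0] carries the running sample index.
    """
    if t >= t_end - 1e-14:
        return t, h, STATUS_END
    _rhs(t, y, k[0], n, a, b, I, A, f0)
    nsteps = 0
    while t < t_end - 1e-14:
        if h > max_step:
            h = max_step
        if h < _H_MIN:
            return t, h, STATUS_UNDERFLOW
        h_use = h
        if t + h_use > t_end:
            h_use = t_end - t
        err = _try_step(t, y, h_use, n, k, ynew, a, b, I, A, f0, rtol, atol)
        nsteps += 1
        if nsteps > _MAX_STEPS:
            return t, h, STATUS_MAXSTEPS
        if not math.isfinite(err):
            h = 0.5 * h_use
            continue
        if err > 1.0:
            fac = 0.9 * err ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            h = h_use * fac
            continue
        # accepted step
        if ynew[0] >= V_THRESHOLD:
            # bracket the upward crossing inside (t, t + h_use] by bisection
            # on the step fraction; each probe is a full 5th-order step.
            lo = 0.0
            hi = 1.0
            vdot_here = abs(k[0, 0]) + 1e-16
            for _ in range(80):
                if (hi - lo) * h_use * vdot_here < 1e-11:
                    break
                mid = 0.5 * (lo + hi)
                _try_step(t, y, mid * h_use, n, k, ybis, a, b, I, A, f0, rtol, atol)
                if ybis[0] >= V_THRESHOLD:
                    hi = mid
                else:
                    lo = mid
            _try_step(t, y, hi * h_use, n, k, ynew, a, b, I, A, f0, rtol, atol)
            t_cross = t + hi * h_use
            if sample_dt > 0.0:
                idx = samp_state[0]
                while idx < samp_t.shape[0]:
                    ts = t0_samp + idx * sample_dt
                    if ts > t_cross + 1e-12:
                        break
                    th = (ts - t) / (hi * h_use)
                    if th < 0.0:
                        th = 0.0
                    samp_t[idx] = ts
                    samp_v[idx] = _hermite(th, hi * h_use, y[0], k[0, 0], ynew[0], k[6, 0])
                    samp_u[idx] = _hermite(th, hi * h_use, y[1], k[0, 1], ynew[1], k[6, 1])
                    idx += 1
                samp_state[0] = idx
            for i in range(n):
                y[i] = ynew[i]
            if not math.isfinite(y[0]):
                return t_cross, h, STATUS_NONFINITE
            return t_cross, h, STATUS_SPIKE
        if sample_dt > 0.0:
            idx = samp_state[0]
            t_new = t + h_use
            while idx < samp_t.shape[0]:
                ts = t0_samp + idx * sample_dt
                if ts > t_new + 1e-12:
                    break
                th = (ts - t) / h_use
                if th < 0.0:
                    th = 0.0
                samp_t[idx] = ts
                samp_v[idx] = _hermite(th, h_use, y[0], k[0, 0], ynew[0], k[6, 0])
                samp_u[idx] = _hermite(th, h_use, y[1], k[0, 1], ynew[1], k[6, 1])
                idx += 1
            samp_state[0] = idx
        t = t + h_use
        for i in range(n):
            y[i] = ynew[i]
            k[0, i] = k[6, i]  # FSAL
        if not math.isfinite(y[0]) or not math.isfinite(y[1]):
            return t, h, STATUS_NONFINITE
        if err > 0.0:
            fac = 0.9 * err ** (-0.2)
            if fac > 5.0:
                fac = 5.0
        else:
            fac = 5.0
        h = h_use * fac
    return t, h, STATUS_END


@njit(cache=True)
def run_spikes(
    a,
    b,
    c,
    d,
    I,
    A,
    f0,
    t0,
    v0,
    u0,
    t_end,
    max_spikes,
    rtol,
    atol,
    max_step,
):
    """Integrate with resets, recording spike times and pre-reset u.

    Returns (spike_t, spike_u_pre, n_spikes, t_final, v_final, u_final, status).
    status is STATUS_END (time reached) or STATUS_SPIKE (spike budget hit,
    state left at the post-reset point) or an error code.
    """
    y = np.empty(2, dtype=np.float64)
    y[0] = v0
    y[1] = u0
    k = np.empty((7, 2), dtype=np.float64)
    ynew = np.empty(2, dtype=np.float64)
    ybis = np.empty(2, dtype=np.float64)
    cap = max_spikes if max_spikes > 0 else 1
    spike_t = np.empty(cap, dtype=np.float64)
    spike_u = np.empty(cap, dtype=np.float64)
    ns = 0
    t = t0
    h = 1e-4
    samp_state = np.zeros(1, dtype=np.int64)
    empty = np.empty(0, dtype=np.float64)
    while True:
        t, h, status = _advance(
            y, t, t_end, h, 2, a, b, I, A, f0, rtol, atol, max_step,
            k, ynew, ybis, -1.0, 0.0, samp_state, empty, empty, empty,
        )
        if status == STATUS_SPIKE:
            vdm = _vdot(t, y[0], y[1], I, A, f0)
            if abs(vdm) < GRAZING_GUARD:
                return spike_t[:ns], spike_u[:ns], ns, t, y[0], y[1], STATUS_GRAZING
            spike_t[ns] = t
            spike_u[ns] = y[1]
            ns += 1
            y[0] = c
            y[1] = y[1] + d
            if ns >= max_spikes:
                return spike_t[:ns], spike_u[:ns], ns, t, y[0], y[1], STATUS_SPIKE
        else:
            return spike_t[:ns], spike_u[:ns], ns, t, y[0], y[1], status


@njit(cache=True)
def run_dense(
    a,
    b,
    c,
    d,
    I,
    A,
    f0,
    t0,
    v0,
    u0,
    t_end,
    sample_dt,
    max_spikes,
    rtol,
    atol,
    max_step,
):
    """Like run_spikes but also samples (t, v, u) on a uniform grid."""
    y = np.empty(2, dtype=np.float64)
    y[0] = v0
    y[1] = u0
    k = np.empty((7, 2), dtype=np.float64)
    ynew = np.empty(2, dtype=np.float64)
    ybis = np.empty(2, dtype=np.float64)
    n_samp = int(math.floor((t_end - t0) / sample_dt + 1e-9)) + 1
    samp_t = np.empty(n_samp, dtype=np.float64)
    samp_v = np.empty(n_samp, dtype=np.float64)
    samp_u = np.empty(n_samp, dtype=np.float64)
    samp_state = np.zeros(1, dtype=np.int64)
    empty = np.empty(0, dtype=np.float64)
    cap = max_spikes if max_spikes > 0 else 1
    spike_t = np.empty(cap, dtype=np.float64)
    spike_u = np.empty(cap, dtype=np.float64)
    ns = 0
    t = t0
    h = 1e-4
    status = STATUS_END
    while True:
        t, h, status = _advance(
            y, t, t_end, h, 2, a, b, I, A, f0, rtol, atol, max_step,
            k, ynew, ybis, sample_dt, t0, samp_state, samp_t, samp_v, samp_u,
        )
        if status == STATUS_SPIKE:
            vdm = _vdot(t, y[0], y[1], I, A, f0)
            if abs(vdm) < GRAZING_GUARD:
                status = STATUS_GRAZING
                break
            if ns < max_spikes:
                spike_t[ns] = t
                spike_u[ns] = y[1]
                ns += 1
            y[0] = c
            y[1] = y[1] + d
            if ns >= max_spikes:
                status = STATUS_SPIKE
                break
        else:
            break
    m = samp_state[0]
    return (
        samp_t[:m],
        samp_v[:m],
        samp_u[:m],
        spike_t[:ns],
        spike_u[:ns],
        ns,
        t,
        y[0],
        y[1],
        status,
    )


@njit(cache=True, inline="always")
def _saltation_entries(t, u_pre, a, b, c, d, I, A, f0):
    """Entries (s11, s21) of the saltation matrix at a crossing of v = 30.

    Pre-jump derivatives at (30, u-), post-jump at (c, u- + d), same time.
    """
    vdm = _vdot(t, V_THRESHOLD, u_pre, I, A, f0)
    udm = _udot(V_THRESHOLD, u_pre, a, b)
    vdp = _vdot(t, c, u_pre + d, I, A, f0)
    udp = _udot(c, u_pre + d, a, b)
    s11 = vdp / vdm
    s21 = (udp - udm) / vdm
    return s11, s21, vdm


@njit(cache=True, inline="always")
def _apply_saltation(y6, s11, s21):
    p11 = y6[2]
    p12 = y6[3]
    y6[2] = s11 * p11
    y6[3] = s11 * p12
    y6[4] = s21 * p11 + y6[4]
    y6[5] = s21 * p12 + y6[5]


@njit(cache=True)
def run_lyapunov_segments(
    a,
    b,
    c,
    d,
    I,
    A,
    f0,
    t0,
    v0,
    u0,
    n_segments,
    spikes_per_segment,
    segment_t_max,
    rtol,
    atol,
    max_step,
):
    """Per-segment transition-matrix products for the Lyapunov spectrum.

    Each segment integrates the augmented (state + variational) system from
    the identity, inserting the saltation matrix at every reset, and closes
    after `spikes_per_segment` spikes or `segment_t_max` ms, whichever first.

    Returns (seg_t_start, seg_t_end, seg_nspikes, seg_l1, seg_l2, seg_phi,
    t_final, v_final, u_final, status); seg_l1/seg_l2 are the eigenvalue
    magnitudes of each segment product, sorted descending.
    """
    y = np.empty(6, dtype=np.float64)
    y[0] = v0
    y[1] = u0
    k = np.empty((7, 6), dtype=np.float64)
    ynew = np.empty(6, dtype=np.float64)
    ybis = np.empty(6, dtype=np.float64)
    seg_t_start = np.empty(n_segments, dtype=np.float64)
    seg_t_end = np.empty(n_segments, dtype=np.float64)
    seg_nspikes = np.zeros(n_segments, dtype=np.int64)
    seg_l1 = np.empty(n_segments, dtype=np.float64)
    seg_l2 = np.empty(n_segments, dtype=np.float64)
    seg_phi = np.empty((n_segments, 2, 2), dtype=np.float64)
    samp_state = np.zeros(1, dtype=np.int64)
    empty = np.empty(0, dtype=np.float64)
    t = t0
    h = 1e-4
    status = STATUS_END
    n_done = 0
    for kseg in range(n_segments):
        seg_t_start[kseg] = t
        # Phi := identity at the segment start
        y[2] = 1.0
        y[3] = 0.0
        y[4] = 0.0
        y[5] = 1.0
        t_cap = t + segment_t_max
        nsp = 0
        failed = False
        while nsp < spikes_per_segment:
            t, h, status = _advance(
                y, t, t_cap, h, 6, a, b, I, A, f0, rtol, atol, max_step,
                k, ynew, ybis, -1.0, 0.0, samp_state, empty, empty, empty,
            )
            if status == STATUS_SPIKE:
                s11, s21, vdm = _saltation_entries(t, y[1], a, b, c, d, I, A, f0)
                if abs(vdm) < GRAZING_GUARD:
                    status = STATUS_GRAZING
                    failed = True
                    break
                _apply_saltation(y, s11, s21)
                y[0] = c
                y[1] = y[1] + d
                nsp += 1
            elif status == STATUS_END:
                break  # 1000 ms cap before the spike quota
            else:
                failed = True
                break
        if failed:
            break
        seg_t_end[kseg] = t
        seg_nspikes[kseg] = nsp
        p11 = y[2]
        p12 = y[3]
        p21 = y[4]
        p22 = y[5]
        seg_phi[kseg, 0, 0] = p11
        seg_phi[kseg, 0, 1] = p12
        seg_phi[kseg, 1, 0] = p21
        seg_phi[kseg, 1, 1] = p22
        tr = p11 + p22
        det = p11 * p22 - p12 * p21
        disc = 0.25 * tr * tr - det
        if disc >= 0.0:
            rt = math.sqrt(disc)
            e1 = abs(0.5 * tr + rt)
            e2 = abs(0.5 * tr - rt)
        else:
            e1 = math.sqrt(abs(det))
            e2 = e1
        if e2 > e1:
            e1, e2 = e2, e1
        seg_l1[kseg] = e1
        seg_l2[kseg] = e2
        n_done += 1
    return (
        seg_t_start[:n_done],
        seg_t_end[:n_done],
        seg_nspikes[:n_done],
        seg_l1[:n_done],
        seg_l2[:n_done],
        seg_phi[:n_done],
        t,
        y[0],
        y[1],
        status,
    )


@njit(cache=True)
def run_phi_returns(
    a,
    b,
    c,
    d,
    I,
    A,
    f0,
    t0,
    u0_pre,
    n_returns,
    t_max,
    rtol,
    atol,
    max_step,
):
    """Transition matrix over n_returns section returns from (v=30, u0_pre).

    Starts at the post-reset image of the section point, integrates the
    augmented system, multiplies the saltation matrix at each interior
    crossing, and stops at the n-th crossing pre-reset.

    Returns (phi 2x2, t_end, u_pre_end, vdot_end, udot_end, status).
    """
    y = np.empty(6, dtype=np.float64)
    y[0] = c
    y[1] = u0_pre + d
    y[2] = 1.0
    y[3] = 0.0
    y[4] = 0.0
    y[5] = 1.0
    k = np.empty((7, 6), dtype=np.float64)
    ynew = np.empty(6, dtype=np.float64)
    ybis = np.empty(6, dtype=np.float64)
    samp_state = np.zeros(1, dtype=np.int64)
    empty = np.empty(0, dtype=np.float64)
    phi = np.empty((2, 2), dtype=np.float64)
    t = t0
    h = 1e-4
    count = 0
    while True:
        t, h, status = _advance(
            y, t, t0 + t_max, h, 6, a, b, I, A, f0, rtol, atol, max_step,
            k, ynew, ybis, -1.0, 0.0, samp_state, empty, empty, empty,
        )
        if status == STATUS_SPIKE:
            count += 1
            u_pre = y[1]
            vdm = _vdot(t, y[0], u_pre, I, A, f0)
            udm = _udot(y[0], u_pre, a, b)
            if abs(vdm) < GRAZING_GUARD:
                return phi, t, u_pre, vdm, udm, STATUS_GRAZING
            if count == n_returns:
                phi[0, 0] = y[2]
                phi[0, 1] = y[3]
                phi[1, 0] = y[4]
                phi[1, 1] = y[5]
                return phi, t, u_pre, vdm, udm, STATUS_END
            s11, s21, _ = _saltation_entries(t, u_pre, a, b, c, d, I, A, f0)
            _apply_saltation(y, s11, s21)
            y[0] = c
            y[1] = u_pre + d
        elif status == STATUS_END:
            return phi, t, y[1], 0.0, 0.0, STATUS_NO_RETURN
        else:
            return phi, t, y[1], 0.0, 0.0, status


@njit(cache=True)
def rk4_spike_times(a, b, c, d, I, A, f0, t0, v0, u0, t_end, max_spikes, step):
    """Fixed-step classical RK4 with linear-interpolation event location.

    Independent validation integrator; not used by the analysis pipeline.
    """
    spike_t = np.empty(max_spikes, dtype=np.float64)
    ns = 0
    t = t0
    v = v0
    u = u0
    while t < t_end and ns < max_spikes:
        k1v = _vdot(t, v, u, I, A, f0)
        k1u = _udot(v, u, a, b)
        k2v = _vdot(t + 0.5 * step, v + 0.5 * step * k1v, u + 0.5 * step * k1u, I, A, f0)
        k2u = _udot(v + 0.5 * step * k1v, u + 0.5 * step * k1u, a, b)
        k3v = _vdot(t + 0.5 * step, v + 0.5 * step * k2v, u + 0.5 * step * k2u, I, A, f0)
        k3u = _udot(v + 0.5 * step * k2v, u + 0.5 * step * k2u, a, b)
        k4v = _vdot(t + step, v + step * k3v, u + step * k3u, I, A, f0)
        k4u = _udot(v + step * k3v, u + step * k3u, a, b)
        v_new = v + step / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        u_new = u + step / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        t_new = t + step
        if v_new >= V_THRESHOLD:
            # linear event interpolation; resume from the crossing time
            frac = (V_THRESHOLD - v) / (v_new - v)
            spike_t[ns] = t + frac * step
            ns += 1
            v = c
            u = u + frac * step * (k1u + 2.0 * k2u + 2.0 * k3u + k4u) / 6.0 + d
            t = t + frac * step
        else:
            v = v_new
            u = u_new
            t = t_new
    return spike_t[:ns], ns
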