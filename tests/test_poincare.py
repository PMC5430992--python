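"""Section-map analysis: period detection, multipliers, sweeps."""

import numpy as np
import pytest

from chaores import (
    SignalParams,
    characteristic_multiplier,
    detect_period,
    find_periodic_orbit,
    lyapunov_map,
    lyapunov_spectrum,
    refine_orbit_newton,
    section_map,
    section_sequence,
    simulate,
    sweep_bifurcation,
)
from chaores.poincare_bifurcation import SectionSequence


def test_section_sequence_extracts_pre_reset_u(region1):
    traj = simulate(region1.with_d(0.85), t_span=(0.0, 500.0))
    seq = section_sequence(traj)
    assert len(seq) == traj.n_spikes
    assert np.array_equal(seq.u_values, traj.spike_u_pre)
    assert np.all(np.diff(seq.times) > 0)


def test_section_sequence_empty_for_quiescent_run():
    from chaores import NeuronParams, State

    p = NeuronParams(0.02, 0.2, -65.0, 2.0, I=0.0)
    traj = simulate(p, t_span=(0.0, 300.0), init=State(0.0, -70.0, -14.0))
    assert len(section_sequence(traj)) == 0


@pytest.mark.parametrize(
    "values, expected",
    [
        (np.full(600, 2.0), 1),
        (np.tile([1.0, 1.5], 300), 2),
        (np.tile([0.3, 1.1, -0.4, 2.0], 150), 4),
    ],
)
def test_detect_period_simple_sequences(values, expected):
    assert detect_period(values) == expected


def test_detect_period_flags_chaotic_sequence():
    # fully developed logistic map is aperiodic for almost every seed
    x = np.empty(600)
    x[0] = 0.37
    for i in range(599):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    assert detect_period(x) is None


def test_detect_period_requires_enough_data():
    with pytest.raises(ValueError):
        detect_period(np.ones(100))
    seq = SectionSequence(np.ones(600), np.arange(600.0))
    assert detect_period(seq) == 1


def test_multiplier_matches_finite_difference_oracle(region1):
    """The variational multiplier must agree with a brute-force central
    difference of the section map psi^l."""
    p = region1.with_d(0.82)
    orbit = find_periodic_orbit(p)
    assert orbit.period_l == 1
    res = characteristic_multiplier(p, orbit)
    assert res.classification == "stable"
    eps = 1e-6
    up = section_map(p, orbit.u0 + eps, orbit.period_l, t0=orbit.t0)
    dn = section_map(p, orbit.u0 - eps, orbit.period_l, t0=orbit.t0)
    fd = (up - dn) / (2 * eps)
    assert res.mu == pytest.approx(fd, abs=1e-4)


def test_multiplier_fd_oracle_period_two(region1):
    p = region1.with_d(0.85)
    orbit = find_periodic_orbit(p)
    assert orbit.period_l == 2
    res = characteristic_multiplier(p, orbit)
    eps = 1e-6
    fd = (
        section_map(p, orbit.u0 + eps, 2, t0=orbit.t0)
        - section_map(p, orbit.u0 - eps, 2, t0=orbit.t0)
    ) / (2 * eps)
    assert res.mu == pytest.approx(fd, abs=1e-4)
    assert abs(res.mu) < 1.0


def test_newton_refinement_lands_on_fixed_point(region1):
    p = region1.with_d(0.82)
    orbit = find_periodic_orbit(p)
    u_star, mu = refine_orbit_newton(p, orbit.u0 + 1e-3, 1)
    assert abs(section_map(p, u_star, 1) - u_star) < 1e-7
    assert mu == pytest.approx(characteristic_multiplier(p, orbit).mu, abs=1e-6)


def test_period_doubles_across_first_bifurcation(region1):
    """The attractor period goes 1 -> 2 across the first flip point."""
    o_lo = find_periodic_orbit(region1.with_d(0.83), settle=3000)
    o_hi = find_periodic_orbit(region1.with_d(0.84), settle=3000)
    assert o_lo.period_l == 1
    assert o_hi.period_l == 2
    # the doubled cycle straddles the old fixed point
    assert o_hi.u_cycle.min() < o_lo.u_cycle[0] < o_hi.u_cycle.max()


def test_sweep_bifurcation_locates_flip(region1):
    d_values = [0.82, 0.83, 0.84]
    diagram = sweep_bifurcation(
        region1, d_values, n_segments=20, settle=1500, locate_points=True
    )
    assert list(diagram.table["d"]) == d_values
    assert list(diagram.table["period"])[:2] == [1, 1]
    assert diagram.table["period"].iloc[2] == 2
    # lambda_1 ~ 0 on stable branches
    assert np.all(np.abs(diagram.table["lambda1"]) < 5e-3)
    flips = [p for p in diagram.points if p.type == "period_doubling"]
    assert len(flips) == 1
    assert 0.83 <= flips[0].parameter <= 0.84
    lo, hi = flips[0].bracket
    assert hi - lo <= 1e-4
    # tails recorded for plotting
    assert set(diagram.tails) == set(d_values)
    assert all(len(t) <= 64 for t in diagram.tails.values())


def test_sweep_single_point_degenerate(region1):
    diagram = sweep_bifurcation(
        region1, [0.82], n_segments=10, settle=800, locate_points=True
    )
    assert len(diagram.table) == 1
    assert diagram.points == []


def test_sweep_rejects_empty_range(region1):
    with pytest.raises(ValueError):
        sweep_bifurcation(region1, [])


def test_aperiodic_region_has_positive_lambda1(region1):
    """lambda_1 > 0 regions and aperiodic-flag regions coincide."""
    diagram = sweep_bifurcation(
        region1, [0.85, 0.92], n_segments=30, settle=1500, locate_points=False
    )
    periodic = diagram.table.iloc[0]
    chaotic = diagram.table.iloc[1]
    assert periodic["period"] == 2 and abs(periodic["lambda1"]) < 5e-3
    assert np.isnan(chaotic["period"]) and chaotic["lambda1"] > 5e-3


def test_lyapunov_map_single_cell_consistency(region1):
    grid = lyapunov_map(region1, [region1.c], [0.85], n_segments=20)
    assert len(grid) == 1
    direct = lyapunov_spectrum(region1.with_d(0.85), n_segments=20)
    assert grid["lambda1"].iloc[0] == pytest.approx(direct.lambda1, abs=1e-12)
    assert grid["error"].iloc[0] == ""


def test_lyapunov_map_grid_shape(region2):
    grid = lyapunov_map(region2, [-56.0, -55.0], [-12.0, -16.0], n_segments=10)
    assert len(grid) == 4
    assert grid["lambda1"].notna().all()


def test_forced_section_analysis_runs(region1, weak_signal):
    """Section tools accept the forced flow as well."""
    orbit = find_periodic_orbit(region1.with_d(0.82), signal=weak_signal, settle=800)
    # weak forcing detunes the orbit: it is generically quasiperiodic, so
    # either outcome (None or small l) is acceptable; the call must not fail
    if orbit is not None:
        assert orbit.period_l >= 1
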