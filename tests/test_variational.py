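"""Variational flow: Jacobian, saltation structure, Lyapunov accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from chaores import (
    NeuronParams,
    SignalParams,
    State,
    characteristic_multiplier,
    find_periodic_orbit,
    jacobian,
    lyapunov_spectrum,
    saltation_matrix,
    segment_transition_matrix,
    spectrum_from_segments,
)
from chaores.hybrid_model import GrazingError


def test_jacobian_hand_values():
    p = NeuronParams(0.02, 0.2, -65.0, 2.0, I=0.0)
    j = jacobian(State(0.0, 0.0, 0.0), p)
    assert np.allclose(j, [[5.0, -1.0], [0.004, -0.02]], atol=1e-15)
    # top-left entry vanishes at v = -62.5
    j = jacobian(State(0.0, -62.5, 3.0), p)
    assert j[0, 0] == pytest.approx(0.0, abs=1e-13)
    # a = 0 kills the u-row
    p0 = NeuronParams(0.0, 0.2, -65.0, 2.0, I=0.0)
    j = jacobian(State(0.0, 12.0, -3.0), p0)
    assert j[1, 0] == 0.0 and j[1, 1] == 0.0


def test_saltation_hand_example():
    # a=0.02, b=0.2, c=-55, I=10, u-=0, d=1:
    #   v'(-) = 0.04*900 + 150 + 140 + 10 = 336,   u'(-) = 0.02*6 = 0.12
    #   v'(+) = 0.04*3025 - 275 + 140 - 1 + 10 = -5, u'(+) = 0.02*(-11-1) = -0.24
    p = NeuronParams(0.02, 0.2, -55.0, 1.0, I=10.0)
    s = saltation_matrix(State(0.0, 30.0, 0.0), p)
    assert s.entries[0, 0] == pytest.approx(-5.0 / 336.0, rel=1e-12)
    assert s.entries[1, 0] == pytest.approx(-0.36 / 336.0, rel=1e-12)
    assert s.entries[0, 1] == 0.0
    assert s.entries[1, 1] == 1.0


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    u=st.floats(-20.0, 20.0),
    d=st.floats(-15.0, 5.0),
    c=st.floats(-70.0, -40.0),
    t=st.floats(0.0, 100.0),
)
def test_saltation_structural_entries_exact(u, d, c, t):
    """Entries (0,1) = 0 and (1,1) = 1 hold exactly for any crossing."""
    p = NeuronParams(0.02, 0.2, c, d, I=10.0)
    s = saltation_matrix(State(t, 30.0, u), p, SignalParams(0.01, 0.1))
    assert s.entries[0, 1] == 0.0
    assert s.entries[1, 1] == 1.0
    # determinant equals the velocity ratio across the jump
    det = np.linalg.det(s.entries)
    assert det == pytest.approx(s.entries[0, 0], rel=1e-12)


def test_saltation_approaches_identity_for_jump_free_reset():
    # c -> 30, d = 0 leaves the state unchanged, so S -> identity
    p = NeuronParams(0.02, 0.2, 30.0 - 1e-9, 0.0, I=10.0)
    s = saltation_matrix(State(0.0, 30.0, 2.0), p)
    assert np.allclose(s.entries, np.eye(2), atol=1e-8)


def test_saltation_rejects_off_section_state():
    p = NeuronParams(0.02, 0.2, -55.0, 1.0, I=10.0)
    with pytest.raises(ValueError):
        saltation_matrix(State(0.0, 10.0, 0.0), p)


def test_saltation_grazing_guard():
    # choose u- so that v'(-) = 326 - u + I = 0 exactly
    p = NeuronParams(0.02, 0.2, -55.0, 1.0, I=0.0)
    with pytest.raises(GrazingError):
        saltation_matrix(State(0.0, 30.0, 326.0), p)


def test_spectrum_accumulation_matches_constant_jacobian():
    """Per-segment products of expm(J dt) give back J's eigenvalues."""
    J = np.array([[-0.15, 0.05], [0.05, -0.15]])  # eigenvalues -0.1, -0.2
    dt = 7.3
    mats = [expm(J * dt)] * 40
    lam1, lam2 = spectrum_from_segments(mats, 0.0, 40 * dt)
    assert lam1 == pytest.approx(-0.1, abs=1e-9)
    assert lam2 == pytest.approx(-0.2, abs=1e-9)


def test_spectrum_accumulation_complex_pair():
    """A rotation+contraction has a complex pair; both moduli are used."""
    J = np.array([[-0.05, -1.0], [1.0, -0.05]])
    mats = [expm(J * 2.0)] * 10
    lam1, lam2 = spectrum_from_segments(mats, 0.0, 20.0)
    assert lam1 == pytest.approx(-0.05, abs=1e-9)
    assert lam2 == pytest.approx(-0.05, abs=1e-9)


def test_zero_length_segment_is_identity(region1):
    seg = segment_transition_matrix(region1, State(3.0, -60.0, -12.0), 3.0)
    assert np.array_equal(seg.matrix, np.eye(2))
    assert seg.n_spikes == 0


def test_spikefree_segment_matches_smooth_variational_flow():
    """Without resets the transition matrix solves dPhi/dt = J Phi; compare
    against a product of short-interval matrix exponentials."""
    p = NeuronParams(0.02, 0.2, -65.0, 2.0, I=0.0)
    init = State(0.0, -70.0, -14.0)  # rest point: J is constant here
    seg = segment_transition_matrix(p, init, 400.0)
    expected = expm(np.array([[0.08 * -70.0 + 5.0, -1.0], [p.a * p.b, -p.a]]) * 400.0)
    assert seg.n_spikes == 0
    assert np.allclose(seg.matrix, expected, rtol=1e-7, atol=1e-12)


def test_stable_limit_cycle_has_zero_lambda1(region1):
    """A stable periodic orbit of the flow keeps lambda_1 at 0 (the neutral
    direction along the orbit) and lambda_2 < 0."""
    spec = lyapunov_spectrum(region1.with_d(0.85))
    assert abs(spec.lambda1) < 5e-3
    assert spec.lambda2 < -0.01
    assert spec.lambda1 >= spec.lambda2
    assert spec.n_segments == 50


def test_chaotic_regime_spectrum_signs(region1):
    spec = lyapunov_spectrum(region1.with_d(0.92))
    assert spec.lambda1 > 0.01
    assert abs(spec.lambda2) < 5e-3


def test_spectrum_converges_with_segment_count(region1):
    s1 = lyapunov_spectrum(region1.with_d(0.92), n_segments=40)
    s2 = lyapunov_spectrum(region1.with_d(0.92), n_segments=80)
    assert abs(s1.lambda1 - s2.lambda1) < 1e-3


def test_segment_records_follow_20_spike_rule(region1):
    spec = lyapunov_spectrum(region1.with_d(0.85), n_segments=5, keep_segments=True)
    for seg in spec.segments:
        assert seg.n_spikes <= 20
        assert seg.t_end - seg.t_start <= 1000.0 + 1e-9
        assert seg.eigen_magnitudes[0] >= seg.eigen_magnitudes[1]
    df = spec.segments_to_frame()
    assert list(df.columns) == ["t_start", "t_end", "n_spikes", "l1_mag", "l2_mag"]


def test_monodromy_eigenvalue_matches_section_multiplier(region1):
    """The one-period monodromy (variational product with saltation) has
    eigenvalues {~1, ~mu}; its nontrivial eigenvalue must match the
    section-map multiplier pathway."""
    p = region1.with_d(0.85)
    orbit = find_periodic_orbit(p)
    mu = characteristic_multiplier(p, orbit).mu
    init = State(orbit.t0, p.c, orbit.u0 + p.d)  # post-reset anchor
    seg = segment_transition_matrix(p, init, orbit.t0 + orbit.cycle_time + 1e-7)
    eigs = np.sort(np.abs(np.linalg.eigvals(seg.matrix)))
    assert eigs[1] == pytest.approx(1.0, abs=1e-6)
    assert eigs[0] == pytest.approx(abs(mu), abs=1e-6)
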