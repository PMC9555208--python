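from dataclasses import replace

import numpy as np
import pytest

from mothmpc.config import Treatment
from mothmpc.dynamics import (State, Trajectory, center_of_mass,
                              center_of_mass_velocity, derivative_batch,
                              integrate_window, rk4_rollout, state_derivative,
                              total_energy)

from _oracles import lagrangian_accelerations


def conservative(params):
    return replace(params, eta=0.0, Cd=0.0)


def random_state(rng, beta_margin=0.6):
    s = rng.normal(0, 1, 8) * np.array([0.1, 0.1, 1, 1, 0.5, 0.5, 5, 5])
    # keep the flexion angle away from the wrap seam at +-pi
    s[3] = s[2] + np.pi + rng.uniform(-np.pi + beta_margin,
                                      np.pi - beta_margin)
    return s


def test_straight_rest_configuration_is_equilibrium(params, fa):
    p = replace(params, g=0.0, Cd=0.0)
    s = State(theta=0.3, phi=0.3 + np.pi)
    d = state_derivative(s, np.zeros(4), p, fa)
    assert np.allclose(d, 0.0, atol=1e-14)


def test_com_acceleration_is_gravity_without_drag(params, fa, rng):
    p = replace(params, Cd=0.0)
    s = random_state(rng)
    d = derivative_batch(s, np.zeros(4), p, fa)
    eps = 1e-7
    a_com = (center_of_mass_velocity(s + eps * d, p)
             - center_of_mass_velocity(s - eps * d, p)) / (2 * eps)
    assert a_com[0] == pytest.approx(0.0, abs=1e-5)
    assert a_com[1] == pytest.approx(-p.g, rel=1e-6)


def test_total_energy_components(params):
    # pure spring deflection: 0.5 * 0.0023 * 0.1^2 = 1.15e-5 J
    p = replace(params, g=0.0)
    s = State(theta=0.0, phi=np.pi + 0.1)
    assert total_energy(s, p) == pytest.approx(1.15e-5)
    # rigid translation: 0.5 (m1 + m2) v^2
    s2 = State(theta=0.2, phi=0.2 + np.pi, xdot=0.3, ydot=-0.4)
    p2 = replace(params, g=0.0)
    assert total_energy(s2, p2) == pytest.approx(
        0.5 * (p2.m1 + p2.m2) * 0.25)


def test_energy_conserved_without_dissipation(params, fa):
    p = conservative(params)
    s0 = State(theta=0.4, phi=0.4 + np.pi + 0.3, thetadot=1.0,
               phidot=-2.0, xdot=0.1)
    traj = integrate_window(s0, np.zeros(4), 1.0, p, fa,
                            rtol=1e-9, atol=1e-12)
    E = total_energy(traj.states, p)
    drift = np.max(np.abs(E - E[0])) / abs(E[0])
    assert drift < 1e-6


def test_ballistic_com_parabola(params, fa):
    p = replace(params, Cd=0.0)
    s0 = State(theta=0.5, phi=0.5 + np.pi, xdot=0.2, ydot=0.3,
               thetadot=1.0, phidot=0.5)
    traj = integrate_window(s0, np.zeros(4), 0.5, p, fa,
                            rtol=1e-9, atol=1e-12)
    com0 = center_of_mass(s0.as_array(), p)
    v0 = center_of_mass_velocity(s0.as_array(), p)
    t = traj.times[:, None]
    expected = com0 + v0 * t + 0.5 * np.array([0.0, -p.g]) * t**2
    com = center_of_mass(traj.states, p)
    assert np.allclose(com, expected, atol=1e-8)


def test_internal_abdominal_torque_preserves_com_velocity(params, fa):
    p = replace(params, g=0.0, Cd=0.0)
    s0 = State(theta=1.0, phi=1.0 + np.pi + 0.2)
    efforts = np.array([0.0, 0.0, 0.008, 0.0])  # tau_abdo only
    traj = integrate_window(s0, efforts, 0.5, p, fa, rtol=1e-9, atol=1e-12)
    v = center_of_mass_velocity(traj.states, p)
    assert np.allclose(v, v[0], atol=1e-8)


def test_matches_lagrangian_oracle_on_random_states(params):
    rng = np.random.default_rng(42)
    for _ in range(100):
        tr = Treatment(actuation=rng.choice(["fa", "fs", "ua", "us"]),
                       abdomen=rng.choice(["regular", "reduced"]))
        s = random_state(rng)
        eff = rng.uniform(0, 1, 4) * np.array([0.443, 2 * np.pi, 0.01, 0.01])
        a_oracle = lagrangian_accelerations(s, eff, params, tr)
        a_analytic = derivative_batch(s, eff, params, tr)[4:]
        scale = np.abs(a_analytic).max()
        assert np.max(np.abs(a_oracle - a_analytic)) / scale < 1e-6


def test_frame_rotation_equivariance(params):
    """Rotating the initial state by a common angle rotates the whole
    trajectory (gravity off; the force direction is body-fixed)."""
    p = replace(params, g=0.0)
    tr = Treatment("fs")
    delta = 0.7
    c, s_ = np.cos(delta), np.sin(delta)
    R = np.array([[c, -s_], [s_, c]])
    s0 = np.array([0.02, -0.01, 0.3, 0.3 + np.pi + 0.2, 0.1, 0.2, 1.0, -0.5])
    rot = s0.copy()
    rot[0:2] = R @ s0[0:2]
    rot[4:6] = R @ s0[4:6]
    rot[2] += delta
    rot[3] += delta
    eff = np.array([0.2, 0.8, 0.003, 0.002])
    t1 = integrate_window(s0, eff, 0.1, p, tr, rtol=1e-10, atol=1e-13)
    t2 = integrate_window(rot, eff, 0.1, p, tr, rtol=1e-10, atol=1e-13)
    assert np.allclose(t2.states[:, 0:2], t1.states[:, 0:2] @ R.T, atol=1e-7)
    assert np.allclose(t2.states[:, 2], t1.states[:, 2] + delta, atol=1e-7)
    assert np.allclose(t2.states[:, 3], t1.states[:, 3] + delta, atol=1e-7)


def test_rk4_screening_agrees_with_adaptive_reference(params, fa, rng):
    s0 = random_state(rng)
    eff = np.array([0.3, 0.5, 0.004, 0.002])
    t_ref = integrate_window(s0, eff, 0.02, params, fa,
                             rtol=1e-10, atol=1e-13)
    times, paths = rk4_rollout(s0[None, :], eff[None, :], 0.02, 5e-4,
                               params, fa)
    assert np.allclose(times, t_ref.times)
    # per-component scale: RK4 truncation must stay far below state scale
    scale = np.abs(t_ref.states).max(axis=0) + 1e-3
    assert np.max(np.abs(paths[0] - t_ref.states) / scale) < 1e-5


def test_passive_eigenfrequencies_match_oracle_linearization(params, fa):
    """Eigenfrequencies of the dynamics linearized about the hanging rest
    configuration agree between the analytic equations and the
    finite-difference Lagrangian oracle to 4 significant digits."""
    p = conservative(params)
    rest = State(theta=np.pi / 2, phi=3 * np.pi / 2).as_array()

    def jac(f):
        eps = 1e-6
        J = np.zeros((8, 8))
        for i in range(8):
            d = np.zeros(8)
            d[i] = eps
            J[:, i] = (f(rest + d) - f(rest - d)) / (2 * eps)
        return J

    zero_eff = np.zeros(4)
    J_analytic = jac(lambda s: derivative_batch(s, zero_eff, p, fa))
    J_oracle = jac(lambda s: np.concatenate(
        [s[4:], lagrangian_accelerations(s, zero_eff, p, fa)]))
    w_a = np.sort(np.abs(np.imag(np.linalg.eigvals(J_analytic))))
    w_o = np.sort(np.abs(np.imag(np.linalg.eigvals(J_oracle))))
    nz_a, nz_o = w_a[w_a > 1e-3], w_o[w_o > 1e-3]
    assert len(nz_a) == len(nz_o)
    assert np.allclose(nz_a, nz_o, rtol=1e-4)


def test_trajectory_validation_and_export(params, fa):
    with pytest.raises(ValueError, match="increasing"):
        Trajectory(times=np.array([0.0, 0.0]), states=np.zeros((2, 8)))
    s0 = State(theta=np.pi / 2, phi=3 * np.pi / 2)
    traj = integrate_window(s0, np.zeros(4), 0.02, params, fa)
    df = traj.to_dataframe()
    assert list(df.columns)[:3] == ["time", "x", "y"]
    assert len(df) == 41  # 0.5 ms grid over 20 ms


def test_non_finite_state_rejected(params, fa):
    s = np.zeros(8)
    s[0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        state_derivative(s, np.zeros(4), params, fa)
    with pytest.raises(ValueError, match="finite"):
        State(x=np.inf)
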