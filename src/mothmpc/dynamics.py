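"""Planar two-body rigid dynamics of the head-thorax + abdomen model.

Geometry and conventions
------------------------
The head-thorax ellipsoid (mass ``m1``, inertia ``I1``) carries the model
reference point at its centre ``(x, y)``; its long axis points along the
angle ``theta`` (counter-clockwise from +x). A pin joint sits a distance
``L1`` tail-ward of the centre, at ``(x - L1 cos(theta), y - L1 sin(theta))``.
The abdomen ellipsoid (``m2``, ``I2``) hangs off the joint with its centre a
distance ``L2`` along its own axis angle ``phi``:

    r2 = (x - L1 cos(theta) + L2 cos(phi),
          y - L1 sin(theta) + L2 sin(phi)).

Abdominal flexion is ``beta = phi - theta - pi``; ``beta = 0`` means the two
long axes are anti-aligned, i.e. a straight body. A torsional spring
(``kappa``, rest at ``beta = 0``) and damper (``eta``) act across the joint.

The equations of motion follow from the Euler-Lagrange form
``d/dt dT/dqdot - dT/dq + dV/dq + dD/dqdot = Q`` with generalized
coordinates ``q = (x, y, theta, phi)``. The closed-form mass matrix and
velocity terms below were derived by hand from the kinetic energy and are
guarded by a finite-difference Lagrangian oracle in the test suite.

Applied efforts: an aerodynamic force of magnitude ``F`` at angle ``alpha``
relative to the head-thorax axis (world angle ``theta + alpha``), applied at
the reference point (``fa``/``ua``) or at the point offset ``+L3`` along the
head-thorax axis (``fs``/``us``, adding the implicit torque
``L3 F sin(alpha)``); a wing torque on ``theta`` (zeroed for ``ua``/``us``);
and an abdominal joint torque acting as an action-reaction pair (``+tau`` on
``phi``, ``-tau`` on ``theta``).

Aerodynamic drag is a pluggable law; the default is quadratic blunt-body
drag ``-0.5 rho Cd A_i |v_i| v_i`` on each mass centre.

Angles are never wrapped during integration; ``beta`` is computed from the
unwrapped values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .config import MothParameters, Treatment, effective_parameters

__all__ = [
    "State",
    "Trajectory",
    "IntegrationError",
    "quadratic_blunt_drag",
    "no_drag",
    "state_derivative",
    "derivative_batch",
    "integrate_window",
    "rk4_rollout",
    "total_energy",
    "center_of_mass",
    "center_of_mass_velocity",
]

STATE_FIELDS = ("x", "y", "theta", "phi", "xdot", "ydot", "thetadot", "phidot")

DragLaw = Callable[[np.ndarray, float, MothParameters], np.ndarray]


class IntegrationError(RuntimeError):
    """The adaptive integrator failed to complete a window."""


@dataclass(frozen=True)
class State:
    """Generalized coordinates and velocities of the two-body model."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0
    phi: float = np.pi
    xdot: float = 0.0
    ydot: float = 0.0
    thetadot: float = 0.0
    phidot: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("state entries must be finite")

    @property
    def beta(self) -> float:
        """Abdominal flexion phi - theta - pi (0 = straight body)."""
        return self.phi - self.theta - np.pi

    @property
    def betadot(self) -> float:
        return self.phidot - self.thetadot

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "State":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected shape (8,), got {arr.shape}")
        return cls(*arr)


@dataclass(frozen=True)
class Trajectory:
    """States on a fixed dense-output time grid."""

    times: np.ndarray   # (m,)
    states: np.ndarray  # (m, 8)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def initial_state(self) -> np.ndarray:
        return self.states[0]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        return df


# ---------------------------------------------------------------------------
# Drag laws

def quadratic_blunt_drag(v: np.ndarray, area: float,
                         params: MothParameters) -> np.ndarray:
    """Blunt-body drag -0.5 rho Cd A |v| v opposing the velocity ``v``.

    ``v`` has shape (..., 2); the returned force has the same shape.
    """
    speed = np.sqrt(np.sum(v * v, axis=-1, keepdims=True))
    return -0.5 * params.rho_a * params.Cd * area * speed * v


def no_drag(v: np.ndarray, area: float, params: MothParameters) -> np.ndarray:
    return np.zeros_like(v)


# ---------------------------------------------------------------------------
# Equations of motion

def _accelerations(q: np.ndarray, qd: np.ndarray, efforts: np.ndarray,
                   p: MothParameters, shifted: bool, wing_on: bool,
                   drag_law: DragLaw) -> np.ndarray:
    """Solve M(q) qdd = Q - h(q, qd) - dV/dq - dD/dqd for qdd.

    All inputs broadcast over leading batch axes: ``q``/``qd`` are (..., 4)
    and ``efforts`` (..., 4) columns (F, alpha, tau_abdo, tau_wing).
    """
    th, ph = q[..., 2], q[..., 3]
    xd, yd, thd, phd = qd[..., 0], qd[..., 1], qd[..., 2], qd[..., 3]
    F, alpha, tau_a = efforts[..., 0], efforts[..., 1], efforts[..., 2]
    tau_w = efforts[..., 3] if wing_on else np.zeros_like(F)

    m2, L1, L2 = p.m2, p.L1, p.L2
    M = p.m1 + m2
    J1 = p.I1 + m2 * L1**2
    J2 = p.I2 + m2 * L2**2
    a = m2 * L1
    b = m2 * L2
    k = m2 * L1 * L2

    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    c12 = np.cos(th - ph)
    s12 = np.sin(th - ph)

    shape = np.broadcast_shapes(th.shape, F.shape)
    zeros = np.zeros(shape)

    Mmat = np.empty(shape + (4, 4))
    Mmat[..., 0, 0] = M
    Mmat[..., 0, 1] = 0.0
    Mmat[..., 0, 2] = a * st
    Mmat[..., 0, 3] = -b * sp
    Mmat[..., 1, 0] = 0.0
    Mmat[..., 1, 1] = M
    Mmat[..., 1, 2] = -a * ct
    Mmat[..., 1, 3] = b * cp
    Mmat[..., 2, 0] = a * st
    Mmat[..., 2, 1] = -a * ct
    Mmat[..., 2, 2] = J1
    Mmat[..., 2, 3] = -k * c12
    Mmat[..., 3, 0] = -b * sp
    Mmat[..., 3, 1] = b * cp
    Mmat[..., 3, 2] = -k * c12
    Mmat[..., 3, 3] = J2

    # velocity-product terms of d/dt dT/dqdot - dT/dq
    h = np.empty(shape + (4,))
    h[..., 0] = a * ct * thd**2 - b * cp * phd**2
    h[..., 1] = a * st * thd**2 - b * sp * phd**2
    h[..., 2] = -k * s12 * phd**2
    h[..., 3] = k * s12 * thd**2

    # gradients of the potential (gravity + torsional spring); the spring
    # acts on the wrapped flexion angle by default, so a full abdominal
    # revolution returns the joint to its rest state
    beta = ph - th - np.pi
    if p.wrap_spring:
        beta = np.arctan2(np.sin(beta), np.cos(beta))
    dV = np.empty(shape + (4,))
    dV[..., 0] = 0.0
    dV[..., 1] = M * p.g
    dV[..., 2] = -m2 * p.g * L1 * ct - p.kappa * beta
    dV[..., 3] = m2 * p.g * L2 * cp + p.kappa * beta

    # Rayleigh damping of the joint
    betadot = phd - thd
    dD = np.empty(shape + (4,))
    dD[..., 0] = 0.0
    dD[..., 1] = 0.0
    dD[..., 2] = -p.eta * betadot
    dD[..., 3] = p.eta * betadot

    # applied efforts
    world = th + alpha
    Q = np.empty(shape + (4,))
    Q[..., 0] = F * np.cos(world)
    Q[..., 1] = F * np.sin(world)
    # moment of the applied force about the reference point: the force acts
    # at the body-fixed point (L3 if shifted else 0) along the axis and
    # h_wing dorsally (the wing hinge sits above the long axis)
    ax = p.L3 if shifted else 0.0
    Q[..., 2] = tau_w - tau_a + F * (ax * np.sin(alpha)
                                     - p.h_wing * np.cos(alpha))
    Q[..., 3] = tau_a

    # aerodynamic drag on each mass centre, mapped through the Jacobians
    v1 = np.stack([xd + zeros, yd + zeros], axis=-1)
    v2 = np.stack([xd + L1 * st * thd - L2 * sp * phd,
                   yd - L1 * ct * thd + L2 * cp * phd], axis=-1)
    f1 = drag_law(v1, p.area1, p)
    f2 = drag_law(v2, p.area2, p)
    Q[..., 0] += f1[..., 0] + f2[..., 0]
    Q[..., 1] += f1[..., 1] + f2[..., 1]
    Q[..., 2] += L1 * st * f2[..., 0] - L1 * ct * f2[..., 1]
    Q[..., 3] += -L2 * sp * f2[..., 0] + L2 * cp * f2[..., 1]

    rhs = Q - h - dV - dD
    try:
        return np.linalg.solve(Mmat, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - parameter bug
        raise np.linalg.LinAlgError(
            f"singular mass matrix (parameter bug): {exc}") from exc


def derivative_batch(states: np.ndarray, efforts: np.ndarray,
                     params: MothParameters, treatment: Treatment,
                     drag_law: DragLaw = quadratic_blunt_drag) -> np.ndarray:
    """Time derivative of a batch of states, shape (..., 8) -> (..., 8)."""
    states = np.asarray(states, dtype=float)
    efforts = np.asarray(efforts, dtype=float)
    p = effective_parameters(params, treatment)
    q, qd = states[..., :4], states[..., 4:]
    acc = _accelerations(q, qd, efforts, p, treatment.force_shifted,
                         treatment.wing_torque_enabled, drag_law)
    return np.concatenate([np.broadcast_to(qd, acc.shape), acc], axis=-1)


def state_derivative(state, efforts, params: MothParameters,
                     treatment: Treatment,
                     drag_law: DragLaw = quadratic_blunt_drag) -> np.ndarray:
    """8-component derivative of a single state under constant efforts.

    ``state`` may be a :class:`State` or an (8,) array; ``efforts`` an
    EffortSet-like object with ``as_array`` or a (4,) array.
    """
    arr = state.as_array() if hasattr(state, "as_array") else np.asarray(state, float)
    eff = efforts.as_array() if hasattr(efforts, "as_array") else np.asarray(efforts, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite state")
    return derivative_batch(arr, eff, params, treatment, drag_law)


def integrate_window(state0, efforts, duration: float,
                     params: MothParameters, treatment: Treatment,
                     rtol: float = 1e-6, atol: float = 1e-9,
                     output_step: float = 5e-4, t_start: float = 0.0,
                     drag_law: DragLaw = quadratic_blunt_drag) -> Trajectory:
    """Integrate one control window with an adaptive solver.

    Uses adaptive RK45 (``rtol`` 1e-6 / ``atol`` 1e-9 by default) with dense
    output evaluated on a fixed ``output_step`` grid, so fractional advance
    points are exact grid samples. Efforts are held constant throughout.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    y0 = state0.as_array() if hasattr(state0, "as_array") else np.asarray(state0, float)
    eff = efforts.as_array() if hasattr(efforts, "as_array") else np.asarray(efforts, float)

    def rhs(t, y):
        return derivative_batch(y, eff, params, treatment, drag_law)

    n = int(np.floor(duration / output_step + 1e-9))
    grid = np.arange(n + 1) * output_step
    if grid[-1] < duration - 1e-12:
        grid = np.append(grid, duration)
    sol = solve_ivp(rhs, (0.0, duration), y0, method="RK45",
                    t_eval=grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integrator failed at t={sol.t[-1] if len(sol.t) else 0.0:.6g}: "
            f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}")
    return Trajectory(times=t_start + sol.t, states=sol.y.T.copy())


def rk4_rollout(states0: np.ndarray, efforts: np.ndarray, duration: float,
                step: float, params: MothParameters, treatment: Treatment,
                drag_law: DragLaw = quadratic_blunt_drag
                ) -> tuple[np.ndarray, np.ndarray]:
    """Propagate a batch of realizations with fixed-step classical RK4.

    ``states0`` is (n, 8), ``efforts`` (n, 4); every realization is advanced
    simultaneously on the ``step`` grid. Returns ``(times (m,),
    paths (n, m, 8))`` where ``m = duration/step + 1``. This is the fast
    screening propagator of the Monte-Carlo controller; the adaptive
    :func:`integrate_window` is the reference it is tested against.
    """
    states0 = np.atleast_2d(np.asarray(states0, dtype=float))
    efforts = np.atleast_2d(np.asarray(efforts, dtype=float))
    n_steps = round(duration / step)
    if abs(n_steps * step - duration) > 1e-9:
        raise ValueError("duration must be a multiple of step")
    p = effective_parameters(params, treatment)
    shifted = treatment.force_shifted
    wing_on = treatment.wing_torque_enabled

    def f(y):
        acc = _accelerations(y[..., :4], y[..., 4:], efforts, p,
                             shifted, wing_on, drag_law)
        return np.concatenate([y[..., 4:], acc], axis=-1)

    paths = np.empty((states0.shape[0], n_steps + 1, 8))
    paths[:, 0] = states0
    y = states0
    for i in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * step * k1)
        k3 = f(y + 0.5 * step * k2)
        k4 = f(y + step * k3)
        y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        paths[:, i + 1] = y
    times = np.arange(n_steps + 1) * step
    return times, paths


# ---------------------------------------------------------------------------
# Energies and centre of mass

def _kinetic(arr: np.ndarray, p: MothParameters) -> np.ndarray:
    th, ph = arr[..., 2], arr[..., 3]
    xd, yd, thd, phd = arr[..., 4], arr[..., 5], arr[..., 6], arr[..., 7]
    m2, L1, L2 = p.m2, p.L1, p.L2
    M = p.m1 + m2
    J1 = p.I1 + m2 * L1**2
    J2 = p.I2 + m2 * L2**2
    return (0.5 * M * (xd**2 + yd**2) + 0.5 * J1 * thd**2 + 0.5 * J2 * phd**2
            + m2 * L1 * (xd * np.sin(th) - yd * np.cos(th)) * thd
            + m2 * L2 * (-xd * np.sin(ph) + yd * np.cos(ph)) * phd
            - m2 * L1 * L2 * np.cos(th - ph) * thd * phd)


def total_energy(state, params: MothParameters) -> float | np.ndarray:
    """Kinetic + gravitational + torsional-spring energy (J).

    Gravitational potential is measured from y = 0 for both mass centres.
    """
    arr = state.as_array() if hasattr(state, "as_array") else np.asarray(state, float)
    p = params
    y, th, ph = arr[..., 1], arr[..., 2], arr[..., 3]
    beta = ph - th - np.pi
    if p.wrap_spring:
        beta = np.arctan2(np.sin(beta), np.cos(beta))
    y2 = y - p.L1 * np.sin(th) + p.L2 * np.sin(ph)
    V = p.m1 * p.g * y + p.m2 * p.g * y2 + 0.5 * p.kappa * beta**2
    return _kinetic(arr, p) + V


def center_of_mass(state, params: MothParameters) -> np.ndarray:
    """System centre of mass, shape (..., 2)."""
    arr = state.as_array() if hasattr(state, "as_array") else np.asarray(state, float)
    p = params
    x, y, th, ph = arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]
    x2 = x - p.L1 * np.cos(th) + p.L2 * np.cos(ph)
    y2 = y - p.L1 * np.sin(th) + p.L2 * np.sin(ph)
    M = p.m1 + p.m2
    return np.stack([(p.m1 * x + p.m2 * x2) / M,
                     (p.m1 * y + p.m2 * y2) / M], axis=-1)


def center_of_mass_velocity(state, params: MothParameters) -> np.ndarray:
    """Velocity of the system centre of mass, shape (..., 2)."""
    arr = state.as_array() if hasattr(state, "as_array") else np.asarray(state, float)
    p = params
    th, ph = arr[..., 2], arr[..., 3]
    xd, yd, thd, phd = arr[..., 4], arr[..., 5], arr[..., 6], arr[..., 7]
    v2x = xd + p.L1 * np.sin(th) * thd - p.L2 * np.sin(ph) * phd
    v2y = yd - p.L1 * np.cos(th) * thd + p.L2 * np.cos(ph) * phd
    M = p.m1 + p.m2
    return np.stack([(p.m1 * xd + p.m2 * v2x) / M,
                     (p.m1 * yd + p.m2 * v2y) / M], axis=-1)
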