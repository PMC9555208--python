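"""Independent numerical oracles used by the test suite.

The Lagrangian oracle assembles the equations of motion purely from scalar
energy functions by finite differences — no hand-derived mass matrix or
Coriolis terms — and therefore checks the analytic implementation against
the variational definition itself.
"""

from __future__ import annotations

import numpy as np

from mothmpc.config import MothParameters, Treatment, effective_parameters


def _r1(q, p):
    return np.array([q[0], q[1]])


def _r2(q, p):
    x, y, th, ph = q
    return np.array([x - p.L1 * np.cos(th) + p.L2 * np.cos(ph),
                     y - p.L1 * np.sin(th) + p.L2 * np.sin(ph)])


def _body_velocity(rfun, q, qd, p, eps=1e-20):
    """d/dt rfun(q) without hand-derived velocity formulas.

    Complex-step differentiation along the direction qd: exact to machine
    precision (no subtractive cancellation), which matters because the
    inertia-scale entries assembled from T are ~1e-6.
    """
    return np.imag(rfun(q + 1j * eps * qd, p)) / eps


def kinetic(q, qd, p: MothParameters) -> float:
    v1 = _body_velocity(_r1, q, qd, p)
    v2 = _body_velocity(_r2, q, qd, p)
    return float(0.5 * p.m1 * v1 @ v1 + 0.5 * p.m2 * v2 @ v2
                 + 0.5 * p.I1 * qd[2] ** 2 + 0.5 * p.I2 * qd[3] ** 2)


def potential(q, p: MothParameters) -> float:
    beta = q[3] - q[2] - np.pi
    if p.wrap_spring:
        beta = np.arctan2(np.sin(beta), np.cos(beta))
    return float(p.m1 * p.g * _r1(q, p)[1] + p.m2 * p.g * _r2(q, p)[1]
                 + 0.5 * p.kappa * beta ** 2)


def rayleigh(q, qd, p: MothParameters) -> float:
    """Joint damping plus the dissipation function of quadratic drag.

    For a drag force -k |v| v the Rayleigh function is (k/3) |v|^3 with
    k = rho Cd A / 2.
    """
    v1 = _body_velocity(_r1, q, qd, p)
    v2 = _body_velocity(_r2, q, qd, p)
    d = 0.5 * p.eta * (qd[3] - qd[2]) ** 2
    for v, area in ((v1, p.area1), (v2, p.area2)):
        k = 0.5 * p.rho_a * p.Cd * area
        d += (k / 3.0) * np.linalg.norm(v) ** 3
    return float(d)


def _force_point(q, p, shifted):
    """World position of the applied-force origin (wing hinge)."""
    x, y, th, _ = q
    ax = p.L3 if shifted else 0.0
    c, s = np.cos(th), np.sin(th)
    return np.array([x + ax * c - p.h_wing * s,
                     y + ax * s + p.h_wing * c])


def generalized_forces(q, efforts, p, shifted, wing_on, eps=1e-6):
    """Applied efforts via virtual work, with the force arm by FD."""
    F, alpha, tau_a, tau_w = efforts
    if not wing_on:
        tau_w = 0.0
    world = q[2] + alpha
    fvec = F * np.array([np.cos(world), np.sin(world)])
    Q = np.zeros(4)
    for i in range(4):
        dq = np.zeros(4)
        dq[i] = eps
        drp = (_force_point(q + dq, p, shifted)
               - _force_point(q - dq, p, shifted)) / (2 * eps)
        # the force direction rotates with theta; hold it fixed during the
        # virtual displacement (it is an applied effort, not a potential)
        Q[i] = fvec @ drp
    Q[2] += tau_w - tau_a
    Q[3] += tau_a
    return Q


def lagrangian_accelerations(state8, efforts4, params: MothParameters,
                             treatment: Treatment) -> np.ndarray:
    """Accelerations from finite differences of T, V and the Rayleigh
    function: solve  M qdd = Q + dT/dq - (d2T/dqd dq) qd - dV/dq - dD/dqd.
    """
    p = effective_parameters(params, treatment)
    q = np.asarray(state8[:4], dtype=float)
    qd = np.asarray(state8[4:], dtype=float)
    # T is exactly quadratic in qd, so unit steps in qd are truncation-free
    # and keep the tiny inertia-scale entries above roundoff
    h_qd, h_q = 1.0, 1e-4
    eye = np.eye(4)

    # mass matrix: Hessian of T in qd by central second differences
    M = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            M[i, j] = (kinetic(q, qd + h_qd * (eye[i] + eye[j]), p)
                       - kinetic(q, qd + h_qd * (eye[i] - eye[j]), p)
                       - kinetic(q, qd - h_qd * (eye[i] - eye[j]), p)
                       + kinetic(q, qd - h_qd * (eye[i] + eye[j]), p)
                       ) / (4 * h_qd**2)
    M = 0.5 * (M + M.T)

    # mixed term (d2T/dqd_i dq_j) qd_j
    mixed = np.zeros(4)
    for i in range(4):
        for j in range(4):
            d2 = (kinetic(q + h_q * eye[j], qd + h_qd * eye[i], p)
                  - kinetic(q + h_q * eye[j], qd - h_qd * eye[i], p)
                  - kinetic(q - h_q * eye[j], qd + h_qd * eye[i], p)
                  + kinetic(q - h_q * eye[j], qd - h_qd * eye[i], p)
                  ) / (4 * h_qd * h_q)
            mixed[i] += d2 * qd[j]

    grad_q = np.zeros(4)
    grad_V = np.zeros(4)
    grad_D = np.zeros(4)
    for i in range(4):
        dq = h_q * eye[i]
        grad_q[i] = (kinetic(q + dq, qd, p) - kinetic(q - dq, qd, p)) / (2 * h_q)
        grad_V[i] = (potential(q + dq, p) - potential(q - dq, p)) / (2 * h_q)
        grad_D[i] = (rayleigh(q, qd + dq, p) - rayleigh(q, qd - dq, p)) / (2 * h_q)

    Q = generalized_forces(q, efforts4, p, treatment.force_shifted,
                           treatment.wing_torque_enabled)
    return np.linalg.solve(M, Q + grad_q - mixed - grad_V - grad_D)
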