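"""The prescribed flower motion: a sum of eleven prime-frequency sines.

The target oscillates vertically only: ``y_goal(t) = sum_i A_i sin(2 pi f_i
t)`` with frequencies at prime multiples of 0.1 Hz and amplitudes decaying
as 1/f so the per-component velocity amplitude stays flat. The horizontal
goal is fixed at ``x = 0`` and the head-thorax goal angle at ``theta = pi/2``
(body pointing straight up). The abdomen angle is left unconstrained — it is
not penalized by the loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ConfigError, load_defaults

__all__ = ["GoalSpec", "default_goal", "load_goal", "y_goal", "y_goal_rate",
           "goal_state_array", "goal_state"]

N_COMPONENTS = 11


@dataclass(frozen=True)
class GoalSpec:
    """Amplitudes (m) and frequencies (Hz) of the vertical target motion."""

    amplitudes: tuple[float, ...]
    frequencies: tuple[float, ...]
    x_goal: float = 0.0
    theta_goal: float = np.pi / 2

    def __post_init__(self) -> None:
        A = tuple(float(a) for a in self.amplitudes)
        f = tuple(float(v) for v in self.frequencies)
        if len(A) != N_COMPONENTS or len(f) != N_COMPONENTS:
            raise ConfigError(
                f"goal: expected {N_COMPONENTS} amplitudes and frequencies, "
                f"got {len(A)} and {len(f)}")
        if not all(fb > fa for fa, fb in zip(f, f[1:])):
            raise ConfigError("goal: frequencies must be strictly increasing")
        if f[0] <= 0:
            raise ConfigError("goal: frequencies must be positive")
        if not all(b <= a for a, b in zip(A, A[1:])):
            raise ConfigError(
                "goal: amplitudes must be non-increasing with frequency")
        object.__setattr__(self, "amplitudes", A)
        object.__setattr__(self, "frequencies", f)

    @property
    def amplitude_bound(self) -> float:
        """An upper bound on |y_goal|: the sum of absolute amplitudes."""
        return float(np.sum(np.abs(self.amplitudes)))


def default_goal() -> GoalSpec:
    table = load_defaults()["goal"]
    return GoalSpec(amplitudes=tuple(table["amplitudes"]),
                    frequencies=tuple(table["frequencies"]))


def load_goal(path: str | Path | None = None) -> GoalSpec:
    """Goal spec from a config file's [goal] section (defaults if absent)."""
    if path is None:
        return default_goal()
    import tomllib

    table = tomllib.loads(Path(path).read_text()).get("goal")
    if table is None:
        return default_goal()
    base = load_defaults()["goal"]
    merged = {**base, **table}
    return GoalSpec(amplitudes=tuple(merged["amplitudes"]),
                    frequencies=tuple(merged["frequencies"]))


def y_goal(t, spec: GoalSpec):
    """Vertical target position at time(s) ``t`` (m)."""
    t = np.asarray(t, dtype=float)
    A = np.asarray(spec.amplitudes)
    f = np.asarray(spec.frequencies)
    return np.sum(A * np.sin(2 * np.pi * f * t[..., None]), axis=-1)


def y_goal_rate(t, spec: GoalSpec):
    """Vertical target velocity at time(s) ``t`` (m/s), term-wise derivative."""
    t = np.asarray(t, dtype=float)
    A = np.asarray(spec.amplitudes)
    f = np.asarray(spec.frequencies)
    w = 2 * np.pi * f
    return np.sum(A * w * np.cos(w * t[..., None]), axis=-1)


def goal_state_array(t: float, spec: GoalSpec) -> np.ndarray:
    """Full goal state (8,) at time ``t``; phi entries are NaN (unpenalized)."""
    return np.array([
        spec.x_goal,
        float(y_goal(t, spec)),
        spec.theta_goal,
        np.nan,
        0.0,
        float(y_goal_rate(t, spec)),
        0.0,
        np.nan,
    ])


def goal_state(t: float, spec: GoalSpec):
    """Goal state as a :class:`~mothmpc.dynamics.State` (phi set to its
    unconstrained straight-body value for readability)."""
    from .dynamics import State

    g = goal_state_array(t, spec)
    return State(x=g[0], y=g[1], theta=g[2], phi=g[2] + np.pi,
                 xdot=g[4], ydot=g[5], thetadot=g[6], phidot=0.0)
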