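"""Monte-Carlo receding-horizon controller.

Each 20 ms control window draws ``n_realizations`` effort sets uniformly at
random, rolls all of them out from the same initial state with the efforts
held constant, scores the end-of-window state against the goal with a
weighted quadratic loss, and keeps the argmin realization. Only the first
``advance_fraction`` (default 25%) of the winning trajectory is traversed;
the state at that point seeds the next window. Repeating until the total
simulated time is covered yields the stitched flight path.

Randomness is organized as per-window substreams spawned from
``(seed, window_index)``, so any window can be reproduced independently and
results are a pure function of configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import (ControlConfig, EffortRanges, MothParameters, Treatment,
                     default_control, default_parameters, default_ranges)
from .dynamics import (DragLaw, State, Trajectory, quadratic_blunt_drag,
                       rk4_rollout)
from .goal import GoalSpec, default_goal, goal_state_array

__all__ = ["EffortSet", "WindowResult", "SimulationResult", "sample_efforts",
           "loss", "run_window", "run_simulation", "initial_rest_state"]

EFFORT_FIELDS = ("F", "alpha", "tau_abdo", "tau_wing")

# loss penalizes x, y, theta and their rates; phi / phidot are free
_PENALIZED = np.array([0, 1, 2, 4, 5, 6])


@dataclass(frozen=True)
class EffortSet:
    """One draw of applied efforts, held constant over a control window."""

    F: float
    alpha: float
    tau_abdo: float
    tau_wing: float

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.alpha, self.tau_abdo, self.tau_wing])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "EffortSet":
        return cls(*np.asarray(arr, dtype=float))


@dataclass(frozen=True)
class WindowResult:
    """The selected realization of one control window."""

    efforts: EffortSet
    trajectory: Trajectory       # full window on the dense-output grid
    loss_value: float            # batch minimum of the loss
    advance_state: np.ndarray    # state at the advance point (8,)
    advance_index: int           # grid index of the advance point
    window_start_time: float
    realization_index: int


@dataclass(frozen=True)
class SimulationResult:
    """A full receding-horizon run: chained windows plus the stitched path."""

    windows: tuple[WindowResult, ...]
    stitched: Trajectory
    params: MothParameters
    treatment: Treatment
    ranges: EffortRanges
    control: ControlConfig
    goal: GoalSpec
    seed: int

    @property
    def losses(self) -> np.ndarray:
        return np.array([w.loss_value for w in self.windows])


def sample_efforts(n: int, ranges: EffortRanges, treatment: Treatment,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform draws of (F, alpha, tau_abdo, tau_wing), shape (n, 4).

    The force is drawn as a magnitude in [0, F_max] with a direction alpha
    covering the full circle. Torques are drawn as magnitudes up to their
    maxima with, by default, an independent random sign — the planar
    analogue of the (magnitude, direction) force draw. Setting
    ``ranges.signed_torques`` to False restricts draws to non-negative
    torques. The wing-torque column is identically zero for the
    underactuated treatments (``ua``/``us``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = -1.0 if ranges.signed_torques else 0.0
    out = np.empty((n, 4))
    out[:, 0] = rng.uniform(0.0, ranges.F_max, n)
    out[:, 1] = rng.uniform(ranges.alpha_min, ranges.alpha_max, n)
    out[:, 2] = rng.uniform(lo * ranges.tau_abdo_max, ranges.tau_abdo_max, n)
    if treatment.wing_torque_enabled:
        out[:, 3] = rng.uniform(lo * ranges.tau_wing_max,
                                ranges.tau_wing_max, n)
    else:
        out[:, 3] = 0.0
    return out


def loss(final_states: np.ndarray, goal: np.ndarray,
         weights: Sequence[float]) -> np.ndarray:
    """Weighted sum of squared end-of-window deviations.

    Penalizes (x, y, theta, xdot, ydot, thetadot) with weights w1..w6;
    abdomen terms are absent. ``final_states`` is (..., 8), ``goal`` (8,).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (6,):
        raise ValueError("six weights required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    final_states = np.asarray(final_states, dtype=float)
    dev = final_states[..., _PENALIZED] - np.asarray(goal)[_PENALIZED]
    return np.sum(w * dev**2, axis=-1)


def initial_rest_state(spec: GoalSpec) -> State:
    """At rest at the goal: x=0, y=y_goal(0)=0, theta=pi/2, straight body."""
    return State(x=spec.x_goal, y=0.0, theta=spec.theta_goal,
                 phi=spec.theta_goal + np.pi)


def run_window(state0: np.ndarray, t0: float, params: MothParameters,
               treatment: Treatment, ranges: EffortRanges,
               control: ControlConfig, spec: GoalSpec,
               rng: np.random.Generator,
               drag_law: DragLaw = quadratic_blunt_drag) -> WindowResult:
    """Roll out one batch of realizations and select the loss argmin.

    All realizations start from the identical ``state0``; the loss is
    evaluated at the window END against the goal at ``t0 + window`` even
    though only the advance fraction will be traversed. Ties break toward
    the lowest realization index.
    """
    state0 = np.asarray(state0, dtype=float)
    efforts = sample_efforts(control.n_realizations, ranges, treatment, rng)
    states0 = np.broadcast_to(state0, (control.n_realizations, 8))
    times, paths = rk4_rollout(states0, efforts, control.window,
                               control.output_step, params, treatment,
                               drag_law)
    finals = paths[:, -1, :]
    if not np.all(np.isfinite(finals)):
        bad = np.flatnonzero(~np.all(np.isfinite(finals), axis=1))
        if len(bad) == control.n_realizations:
            raise RuntimeError(
                f"window at t0={t0:.4f}: all realizations diverged")
        # diverged realizations can never win
        finals = finals.copy()
        finals[bad] = np.inf
    lam = loss(finals, goal_state_array(t0 + control.window, spec),
               control.weights)
    best = int(np.argmin(lam))
    adv = control.advance_index
    return WindowResult(
        efforts=EffortSet.from_array(efforts[best]),
        trajectory=Trajectory(times=t0 + times, states=paths[best]),
        loss_value=float(lam[best]),
        advance_state=paths[best, adv].copy(),
        advance_index=adv,
        window_start_time=t0,
        realization_index=best,
    )


def run_simulation(params: MothParameters | None = None,
                   treatment: Treatment | None = None,
                   ranges: EffortRanges | None = None,
                   control: ControlConfig | None = None,
                   spec: GoalSpec | None = None,
                   initial_state: State | None = None,
                   drag_law: DragLaw = quadratic_blunt_drag,
                   progress: bool = False) -> SimulationResult:
    """Chain control windows until ``control.total_time`` is covered.

    ``total_time`` must be an integer multiple of the advance interval
    ``advance_fraction * window`` (2000 windows of 5 ms advance at the
    defaults). Each window draws from the substream ``(seed, window_index)``.
    """
    params = params if params is not None else default_parameters()
    treatment = treatment if treatment is not None else Treatment()
    ranges = ranges if ranges is not None else default_ranges()
    control = control if control is not None else default_control()
    spec = spec if spec is not None else default_goal()

    advance = control.advance_time
    n_windows = control.total_time / advance
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError(
            "total_time must be an integer multiple of "
            "advance_fraction * window")
    n_windows = round(n_windows)

    state = (initial_state if initial_state is not None
             else initial_rest_state(spec)).as_array()
    adv = control.advance_index

    windows: list[WindowResult] = []
    seg_times: list[np.ndarray] = []
    seg_states: list[np.ndarray] = []
    t0 = 0.0
    for w in range(n_windows):
        rng = np.random.default_rng([control.seed, w])
        try:
            wr = run_window(state, t0, params, treatment, ranges, control,
                            spec, rng, drag_law)
        except Exception as exc:
            raise RuntimeError(f"window {w} (t0={t0:.4f} s) failed") from exc
        windows.append(wr)
        seg_times.append(wr.trajectory.times[:adv])
        seg_states.append(wr.trajectory.states[:adv])
        state = wr.advance_state
        t0 = round((w + 1) * advance / control.output_step) * control.output_step
        if progress and (w + 1) % 100 == 0:
            print(f"  window {w + 1}/{n_windows} (t = {t0:.2f} s)",
                  flush=True)
    seg_times.append(np.array([t0]))
    seg_states.append(state[None, :])
    stitched = Trajectory(times=np.concatenate(seg_times),
                          states=np.concatenate(seg_states))
    return SimulationResult(windows=tuple(windows), stitched=stitched,
                            params=params, treatment=treatment,
                            ranges=ranges, control=control, goal=spec,
                            seed=control.seed)
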