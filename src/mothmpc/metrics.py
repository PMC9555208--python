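"""Flight-performance metrics and treatment-level statistics.

Per control window the simulator is scored by

* non-dimensional tracking error: planar distance between the end-of-window
  state and the goal, divided by body length 2 (L1 + L2);
* mechanical work: per-step accumulation of |F||dr| plus the rotational
  terms |(r x F) dtheta|, |tau_wing dtheta| and |tau_abdo dbeta|, each in
  absolute value (treatments lacking a term contribute zero for it);
* cost of transport: work / (m1 g distance), a dimensionless energetic
  efficiency referenced to the head-thorax weight.

Treatment groups are compared on per-run medians (one number per full
simulation, avoiding pseudo-replication) with a Kruskal-Wallis omnibus test,
the eta-squared effect size (chi2 - k + 1)/(n - k), and Dunn's pairwise
z-tests with a Bonferroni rule and compact-letter-display groupings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import MothParameters, Treatment, body_length, effective_parameters
from .controller import EffortSet, SimulationResult, WindowResult
from .dynamics import Trajectory
from .goal import GoalSpec, goal_state_array

__all__ = ["DISTANCE_EPS", "tracking_error", "window_work",
           "cost_of_transport", "window_metrics", "run_metrics",
           "run_medians", "ComparisonResult", "compare_treatments"]

#: windows whose path length is below this (m) have undefined cost of transport
DISTANCE_EPS = 1e-9


def tracking_error(final_state: np.ndarray, goal: np.ndarray,
                   body_len: float) -> float:
    """Planar distance to the goal over body length (dimensionless)."""
    if body_len <= 0:
        raise ValueError("body_len must be positive")
    final_state = np.asarray(final_state, dtype=float)
    goal = np.asarray(goal, dtype=float)
    dx = final_state[..., 0] - goal[..., 0]
    dy = final_state[..., 1] - goal[..., 1]
    return np.hypot(dx, dy) / body_len


def _path_increments(traj: Trajectory):
    d = np.diff(traj.states, axis=0)
    dr = np.hypot(d[:, 0], d[:, 1])
    dtheta = d[:, 2]
    dbeta = d[:, 3] - d[:, 2]
    return dr, dtheta, dbeta


def window_work(traj: Trajectory, efforts: EffortSet,
                params: MothParameters, treatment: Treatment) -> float:
    """Mechanical work over a trajectory segment (J).

    Accumulated on the dense output grid: F |dr| for the rectilinear term,
    |L3 F sin(alpha) dtheta| for the moment of the shifted force (zero when
    the force acts at the reference point), |tau_wing dtheta| and
    |tau_abdo dbeta|. Efforts are window-constant.
    """
    if len(traj.states) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    dr, dtheta, dbeta = _path_increments(traj)
    work = efforts.F * np.sum(dr)
    if treatment.force_shifted:
        # moment of the shifted force; the basic treatments apply the force
        # at the reference point and carry no moment term
        moment = params.L3 * efforts.F * np.sin(efforts.alpha)
        work += np.sum(np.abs(moment * dtheta))
    if treatment.wing_torque_enabled:
        work += np.sum(np.abs(efforts.tau_wing * dtheta))
    work += np.sum(np.abs(efforts.tau_abdo * dbeta))
    return float(work)


def cost_of_transport(work: float, params: MothParameters,
                      distance: float) -> float:
    """work / (m1 g distance); raises below the distance epsilon."""
    if distance <= DISTANCE_EPS:
        raise ValueError(
            f"distance {distance:g} m below epsilon {DISTANCE_EPS:g}; "
            "cost of transport undefined")
    return work / (params.m1 * params.g * distance)


def window_metrics(wr: WindowResult, params: MothParameters,
                   treatment: Treatment, spec: GoalSpec,
                   segment: str = "advance") -> dict:
    """Metrics of one window.

    ``segment`` selects the work/distance integration span: ``"advance"``
    (default) uses the traversed 25% path, ``"full"`` the whole window.
    The tracking error is always evaluated at the window end, where the
    loss was evaluated.
    """
    if segment not in ("advance", "full"):
        raise ValueError("segment must be 'advance' or 'full'")
    goal = goal_state_array(wr.trajectory.times[-1], spec)
    err = float(tracking_error(wr.trajectory.final_state, goal,
                               body_length(params)))
    stop = wr.advance_index + 1 if segment == "advance" else len(wr.trajectory.states)
    sub = Trajectory(times=wr.trajectory.times[:stop],
                     states=wr.trajectory.states[:stop])
    work = window_work(sub, wr.efforts, params, treatment)
    dr, _, _ = _path_increments(sub)
    distance = float(np.sum(dr))
    defined = distance > DISTANCE_EPS
    cot = work / (effective_parameters(params, treatment).m1
                  * params.g * distance) if defined else np.nan
    # head-thorax mass is unchanged by the reduced-abdomen treatments, but
    # route through effective_parameters for forward compatibility
    return {"t0": wr.window_start_time, "tracking_error": err, "work": work,
            "distance": distance, "cost_of_transport": cot,
            "cot_defined": defined, "loss": wr.loss_value}


def run_metrics(result: SimulationResult,
                segment: str = "advance") -> pd.DataFrame:
    """Per-window metrics table of a full simulation."""
    rows = [window_metrics(w, result.params, result.treatment, result.goal,
                           segment) for w in result.windows]
    return pd.DataFrame(rows)


def run_medians(result: SimulationResult,
                segment: str = "advance") -> dict:
    """Per-run medians — the unit of replication for group comparisons."""
    df = run_metrics(result, segment)
    ok = df[df["cot_defined"]]
    return {
        "median_tracking_error": float(df["tracking_error"].median()),
        "median_cost_of_transport": float(ok["cost_of_transport"].median()),
        "n_windows": len(df),
        "n_cot_undefined": int((~df["cot_defined"]).sum()),
    }


# ---------------------------------------------------------------------------
# Group comparison: Kruskal-Wallis + Dunn + compact letter display

@dataclass(frozen=True)
class ComparisonResult:
    """Omnibus and pairwise comparison of treatment groups."""

    chi2: float
    df: int
    pvalue: float
    eta_squared: float
    group_medians: dict
    pairwise: pd.DataFrame      # columns: a, b, z, p_raw, reject
    letters: dict               # group -> letter string
    alpha: float
    bonferroni_divisor: float


def _dunn_pairwise(groups: Mapping[str, np.ndarray], alpha: float,
                   divisor: float) -> pd.DataFrame:
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    ranks = stats.rankdata(values)
    n = len(values)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"a": a, "b": b, "z": z, "p_raw": p,
                     "reject": p < alpha / divisor})
    return pd.DataFrame(rows)


def _letter_display(labels: Sequence[str],
                    pairwise: pd.DataFrame) -> dict:
    """Compact letter display by the insert-and-absorb algorithm."""
    groups: list[set] = [set(labels)]
    for _, row in pairwise.iterrows():
        if not row["reject"]:
            continue
        a, b = row["a"], row["b"]
        for g in list(groups):
            if a in g and b in g:
                groups.remove(g)
                groups.extend([g - {a}, g - {b}])
        # absorb subsets
        groups = [g for g in groups
                  if g and not any(g < h for h in groups if h is not g)]
        # deduplicate
        uniq = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    groups.sort(key=lambda g: min(labels.index(x) for x in g))
    letters = {lab: "" for lab in labels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lab in labels:
            if lab in g:
                letters[lab] += ch
    return letters


def compare_treatments(groups: Mapping[str, Sequence[float]],
                       alpha: float = 0.05,
                       bonferroni_divisor: float | None = None
                       ) -> ComparisonResult:
    """Rank-based comparison of >= 2 groups of per-run medians.

    Kruskal-Wallis omnibus (chi2, df, p) with effect size
    eta^2 = (chi2 - k + 1)/(n - k), then Dunn's pairwise z-tests. The
    Bonferroni divisor defaults to the number of pairwise comparisons
    (standard reject-if-p < alpha/m rule) and is exposed because other
    conventions exist.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, arr in arrays.items():
        if len(arr) < 3:
            raise ValueError(f"group {g!r} needs >= 3 runs, got {len(arr)}")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values tied across groups")
    k = len(labels)
    n = len(pooled)
    chi2, p = stats.kruskal(*arrays.values())
    eta_sq = (chi2 - k + 1) / (n - k)
    divisor = (bonferroni_divisor if bonferroni_divisor is not None
               else k * (k - 1) / 2)
    pairwise = _dunn_pairwise(arrays, alpha, divisor)
    letters = _letter_display(labels, pairwise)
    medians = {g: float(np.median(arr)) for g, arr in arrays.items()}
    return ComparisonResult(chi2=float(chi2), df=k - 1, pvalue=float(p),
                            eta_squared=float(eta_sq), group_medians=medians,
                            pairwise=pairwise, letters=letters, alpha=alpha,
                            bonferroni_divisor=float(divisor))
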