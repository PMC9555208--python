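"""Physical parameters, treatment definitions, effort ranges and config I/O.

All quantities are SI and all angles are radians. Numeric defaults live in
the versioned ``defaults.toml`` shipped with the package; code never
hard-codes them.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

__all__ = [
    "ConfigError",
    "MothParameters",
    "Treatment",
    "EffortRanges",
    "ControlConfig",
    "ACTUATIONS",
    "ABDOMEN_SIZES",
    "body_length",
    "effective_parameters",
    "load_defaults",
    "default_parameters",
    "default_treatment",
    "default_ranges",
    "default_control",
    "load_config",
    "write_config",
]

ACTUATIONS = ("fa", "fs", "ua", "us")
ABDOMEN_SIZES = ("regular", "reduced")

TWO_PI = 2.0 * math.pi


class ConfigError(ValueError):
    """A configuration file or object violates the schema or an invariant."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass(frozen=True)
class MothParameters:
    """Morphometric and mechanical constants of the two-ellipsoid model.

    ``m1``/``I1`` describe the head-thorax body, ``m2``/``I2`` the abdomen.
    ``L1`` is the distance from the head-thorax reference point to the pin
    joint, ``L2`` from the joint to the abdomen centre, ``L3`` the offset of
    the applied-force origin along the head-thorax axis (used only by the
    shifted treatments). ``b1``/``b2`` are semi-minor axes, giving the
    elliptical cross-sections used by the blunt-body drag law.
    """

    m1: float
    m2: float
    I1: float
    I2: float
    L1: float
    L2: float
    L3: float
    b1: float
    b2: float
    kappa: float
    eta: float
    Cd: float
    mu_a: float
    rho_a: float
    g: float
    h_wing: float = 0.0
    wrap_spring: bool = True

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "I1", "I2", "L1", "L2", "b1", "b2"):
            _require(getattr(self, name) > 0, name, "must be strictly positive")
        for name in ("kappa", "eta", "Cd", "mu_a", "rho_a", "L3"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        _require(math.isfinite(self.h_wing), "h_wing", "must be finite")
        _require(math.isfinite(self.g), "g", "must be finite")

    @property
    def total_mass(self) -> float:
        return self.m1 + self.m2

    @property
    def area1(self) -> float:
        """Drag cross-section of the head-thorax ellipsoid (m^2)."""
        return math.pi * self.b1**2

    @property
    def area2(self) -> float:
        """Drag cross-section of the abdomen ellipsoid (m^2)."""
        return math.pi * self.b2**2


def body_length(params: MothParameters) -> float:
    """Body length 2 (L1 + L2) used to non-dimensionalize tracking error."""
    return 2.0 * (params.L1 + params.L2)


@dataclass(frozen=True)
class Treatment:
    """Actuation variant and abdomen size of a simulation.

    ``fa``/``fs`` keep the wing torque; ``ua``/``us`` are underactuated
    (wing torque identically zero). ``fs``/``us`` apply the aerodynamic
    force at the L3-shifted point instead of the reference point. The
    ``reduced`` abdomen scales m2 (and, by default, I2) by ``mass_scale``.
    """

    actuation: str = "fa"
    abdomen: str = "regular"
    mass_scale: float = 0.1
    scale_inertia: bool = True

    def __post_init__(self) -> None:
        _require(self.actuation in ACTUATIONS, "actuation",
                 f"must be one of {ACTUATIONS}")
        _require(self.abdomen in ABDOMEN_SIZES, "abdomen",
                 f"must be one of {ABDOMEN_SIZES}")
        _require(0 < self.mass_scale <= 1, "mass_scale", "must be in (0, 1]")

    @property
    def wing_torque_enabled(self) -> bool:
        return self.actuation in ("fa", "fs")

    @property
    def force_shifted(self) -> bool:
        return self.actuation in ("fs", "us")


def effective_parameters(params: MothParameters,
                         treatment: Treatment) -> MothParameters:
    """Parameters after applying the treatment's abdomen scaling."""
    if treatment.abdomen == "regular":
        return params
    changes: dict[str, float] = {"m2": params.m2 * treatment.mass_scale}
    if treatment.scale_inertia:
        changes["I2"] = params.I2 * treatment.mass_scale
    return replace(params, **changes)


@dataclass(frozen=True)
class EffortRanges:
    """Sampling bounds of the randomized applied efforts."""

    F_max: float = 0.443
    alpha_min: float = 0.0
    alpha_max: float = TWO_PI
    tau_abdo_max: float = 0.01
    tau_wing_max: float = 0.01
    signed_torques: bool = True

    def __post_init__(self) -> None:
        _require(self.F_max > 0, "F_max", "must be strictly positive")
        _require(self.alpha_max > self.alpha_min, "alpha_max",
                 "must exceed alpha_min")
        _require(self.tau_abdo_max >= 0, "tau_abdo_max", "must be non-negative")
        _require(self.tau_wing_max >= 0, "tau_wing_max", "must be non-negative")


@dataclass(frozen=True)
class ControlConfig:
    """Receding-horizon loop settings and loss weights."""

    window: float = 0.020
    advance_fraction: float = 0.25
    n_realizations: int = 2500
    total_time: float = 10.0
    output_step: float = 0.0005
    weights: tuple[float, ...] = (1.0e6, 1.0e6, 400.0, 400.0, 400.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.window > 0, "window", "must be strictly positive")
        _require(0 < self.advance_fraction <= 1, "advance_fraction",
                 "must be in (0, 1]")
        _require(self.n_realizations >= 1, "n_realizations", "must be >= 1")
        _require(self.total_time > 0, "total_time", "must be strictly positive")
        _require(self.output_step > 0, "output_step",
                 "must be strictly positive")
        _require(len(self.weights) == 6, "weights", "must have six entries")
        _require(all(w >= 0 for w in self.weights), "weights",
                 "must be non-negative")
        _require(self.seed >= 0, "seed", "must be non-negative")
        # the advance point must fall on the dense-output grid
        n_adv = self.advance_fraction * self.window / self.output_step
        _require(abs(n_adv - round(n_adv)) < 1e-9, "output_step",
                 "advance_fraction * window must be a multiple of output_step")
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))

    @property
    def advance_time(self) -> float:
        return self.advance_fraction * self.window

    @property
    def advance_index(self) -> int:
        return round(self.advance_fraction * self.window / self.output_step)

    @property
    def samples_per_window(self) -> int:
        n = self.window / self.output_step
        _require(abs(n - round(n)) < 1e-9, "output_step",
                 "window must be a multiple of output_step")
        return round(n)


# ---------------------------------------------------------------------------
# Defaults and file I/O

def load_defaults() -> dict[str, Any]:
    """Parsed contents of the packaged ``defaults.toml``."""
    text = resources.files("mothmpc").joinpath("defaults.toml").read_text()
    return tomllib.loads(text)


def _build(cls, table: Mapping[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(
            f"[{section}] unknown keys: {sorted(unknown)}; allowed: {sorted(allowed)}")
    kwargs = dict(table)
    if cls is ControlConfig and "weights" in kwargs:
        kwargs["weights"] = tuple(float(w) for w in kwargs["weights"])
    return cls(**kwargs)


def default_parameters() -> MothParameters:
    return _build(MothParameters, load_defaults()["moth"], "moth")


def default_treatment() -> Treatment:
    return _build(Treatment, load_defaults()["treatment"], "treatment")


def default_ranges() -> EffortRanges:
    return _build(EffortRanges, load_defaults()["efforts"], "efforts")


def default_control() -> ControlConfig:
    return _build(ControlConfig, load_defaults()["control"], "control")


_SECTIONS = ("moth", "treatment", "efforts", "control", "goal")


def load_config(path: str | Path):
    """Load a TOML configuration file.

    Unspecified fields are filled from the packaged defaults. Returns
    ``(MothParameters, Treatment, EffortRanges, ControlConfig)``; the
    optional ``[goal]`` section is consumed by :func:`mothmpc.goal.load_goal`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        user = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: not valid TOML: {exc}") from None
    unknown = set(user) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    base = load_defaults()
    merged = {s: {**base.get(s, {}), **user.get(s, {})} for s in _SECTIONS}
    params = _build(MothParameters, merged["moth"], "moth")
    treatment = _build(Treatment, merged["treatment"], "treatment")
    ranges = _build(EffortRanges, merged["efforts"], "efforts")
    control = _build(ControlConfig, merged["control"], "control")
    return params, treatment, ranges, control


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize value of type {type(v).__name__}")


def write_config(path: str | Path,
                 params: MothParameters,
                 treatment: Treatment,
                 ranges: EffortRanges,
                 control: ControlConfig,
                 goal_table: Mapping[str, Sequence[float]] | None = None) -> None:
    """Write a complete TOML config that round-trips through load_config."""
    sections: list[tuple[str, Mapping[str, Any]]] = [
        ("moth", {f.name: getattr(params, f.name) for f in fields(params)}),
        ("treatment", {f.name: getattr(treatment, f.name)
                       for f in fields(treatment)}),
        ("efforts", {f.name: getattr(ranges, f.name) for f in fields(ranges)}),
        ("control", {f.name: (list(getattr(control, f.name))
                              if f.name == "weights"
                              else getattr(control, f.name))
                     for f in fields(control)}),
    ]
    if goal_table is not None:
        sections.append(("goal", dict(goal_table)))
    lines: list[str] = []
    for name, table in sections:
        lines.append(f"[{name}]")
        for key, value in table.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
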