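"""YAML experiment configuration with a strict, fully-resolved schema.

Unknown keys are rejected outright; every default is materialised into the
resolved :class:`ExperimentConfig`, so dumping a loaded config and loading
it again is the identity.  A commented template ships in
``examples/experiment.yaml``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .fixtures import fixture_names, fixtures
from .params import DeviceParams, DisturbanceProfile, Regulation

__all__ = ["ConfigError", "ExperimentConfig", "load_config", "dump_config"]

EXPERIMENTS = ("simulate", "step", "robustness", "sweep", "qic-check", "silencing")
VARIANTS = ("regulated", "unregulated", "ideal", "full")

_PARAM_KEYS = {
    "T", "D", "kappa_gfp", "kappa_ecf", "Ts", "delta", "lam", "beta",
    "R", "gamma", "actuator_saturation",
}
_REGULATION_KEYS = {"kind", "K", "n"}
_DISTURBANCE_KEYS = {"d", "breakpoints", "values"}
_SWEEP_KEYS = {"axis", "values"}
_SILENCING_KEYS = {"doses", "K_half", "hill_n", "basal", "sensor_max"}
_SOLVER_KEYS = {"rtol", "atol", "points_per_segment"}
_TOP_KEYS = {
    "experiment", "variant", "fixture", "params", "regulation", "disturbance",
    "u1", "t_span", "horizon", "d_active", "epsilon", "sweep", "silencing",
    "solver", "seed", "output",
}


class ConfigError(ValueError):
    """A config file violates the schema; the message names the offending key."""


def _reject_unknown(section: str, mapping: dict, allowed: set) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {', '.join(sorted(map(str, unknown)))}"
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully-resolved experiment description."""

    experiment: str = "step"
    variant: str = "regulated"
    fixture: str | None = None
    params: dict[str, float] = field(default_factory=dict)
    regulation: dict[str, Any] = field(default_factory=lambda: {"kind": "constitutive", "K": 1.0, "n": 1.0})
    disturbance: dict[str, Any] = field(default_factory=lambda: {"d": 0.5})
    u1: float = 0.0
    t_span: tuple[float, float] = (0.0, 10.0)
    horizon: float = 10.0
    d_active: float = 0.5
    epsilon: float = 0.1
    sweep: dict[str, Any] = field(default_factory=lambda: {"axis": "disturbance", "values": []})
    silencing: dict[str, Any] = field(
        default_factory=lambda: {
            "doses": [], "K_half": 30.0, "hill_n": 2.0, "basal": 0.0,
            "sensor_max": 300.0,
        }
    )
    solver: dict[str, float] = field(
        default_factory=lambda: {"rtol": 1e-8, "atol": 1e-10, "points_per_segment": 500}
    )
    seed: int | None = None
    output: str | None = None

    def device_params(self) -> DeviceParams:
        """Materialise DeviceParams from the fixture and/or overrides."""
        if self.fixture is not None:
            base = fixtures(self.fixture)
            if self.params:
                base = replace(base, **self.params)
        else:
            missing = {"T", "D", "kappa_gfp", "kappa_ecf", "Ts", "delta",
                       "lam", "beta", "R", "gamma"} - set(self.params)
            if missing:
                raise ConfigError(
                    "no fixture given and params incomplete; missing: "
                    + ", ".join(sorted(missing))
                )
            base = DeviceParams(**self.params)
        if self.regulation.get("kind", "constitutive") != "constitutive":
            base = replace(base, regulation=Regulation(**self.regulation))
        return base

    def disturbance_profile(self) -> DisturbanceProfile:
        d = self.disturbance
        if "breakpoints" in d or "values" in d:
            return DisturbanceProfile(
                tuple(d.get("breakpoints", ())), tuple(d.get("values", ()))
            )
        return DisturbanceProfile.constant(float(d.get("d", 0.0)))


def _validate(raw: dict) -> ExperimentConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown("config", raw, _TOP_KEYS)

    cfg = ExperimentConfig()
    exp = raw.get("experiment", cfg.experiment)
    if exp not in EXPERIMENTS:
        raise ConfigError(f"experiment must be one of {EXPERIMENTS}, got {exp!r}")
    variant = raw.get("variant", cfg.variant)
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")

    fixture = raw.get("fixture")
    if fixture is not None and fixture not in fixture_names():
        raise ConfigError(
            f"unknown fixture {fixture!r}; available: {', '.join(fixture_names())}"
        )

    params = dict(raw.get("params", {}))
    _reject_unknown("params", params, _PARAM_KEYS)
    params = {k: (None if v is None else float(v)) for k, v in params.items()}

    regulation = {**cfg.regulation, **raw.get("regulation", {})}
    _reject_unknown("regulation", regulation, _REGULATION_KEYS)

    disturbance = dict(raw.get("disturbance", cfg.disturbance))
    _reject_unknown("disturbance", disturbance, _DISTURBANCE_KEYS)
    for v in ([disturbance["d"]] if "d" in disturbance else disturbance.get("values", [])):
        if not (0.0 <= float(v) < 1.0):
            raise ConfigError(f"disturbance values must satisfy 0 <= d < 1, got {v}")

    d_active = float(raw.get("d_active", cfg.d_active))
    if not (0.0 <= d_active < 1.0):
        raise ConfigError(f"d_active must satisfy 0 <= d < 1, got {d_active}")

    sweep = {**cfg.sweep, **raw.get("sweep", {})}
    _reject_unknown("sweep", sweep, _SWEEP_KEYS)
    if sweep["axis"] not in ("gain", "disturbance", "input"):
        raise ConfigError(f"sweep axis must be gain|disturbance|input, got {sweep['axis']!r}")
    sweep["values"] = [float(v) for v in sweep["values"]]

    silencing = {**cfg.silencing, **raw.get("silencing", {})}
    _reject_unknown("silencing", silencing, _SILENCING_KEYS)
    silencing["doses"] = [float(v) for v in silencing["doses"]]

    solver = {**cfg.solver, **raw.get("solver", {})}
    _reject_unknown("solver", solver, _SOLVER_KEYS)

    t_span = raw.get("t_span", list(cfg.t_span))
    if len(t_span) != 2:
        raise ConfigError("t_span must be a [t0, t1] pair")

    seed = raw.get("seed", None)
    return ExperimentConfig(
        experiment=exp,
        variant=variant,
        fixture=fixture,
        params=params,
        regulation=regulation,
        disturbance=disturbance,
        u1=float(raw.get("u1", cfg.u1)),
        t_span=(float(t_span[0]), float(t_span[1])),
        horizon=float(raw.get("horizon", cfg.horizon)),
        d_active=d_active,
        epsilon=float(raw.get("epsilon", cfg.epsilon)),
        sweep=sweep,
        silencing=silencing,
        solver={
            "rtol": float(solver["rtol"]),
            "atol": float(solver["atol"]),
            "points_per_segment": int(solver["points_per_segment"]),
        },
        seed=None if seed is None else int(seed),
        output=raw.get("output"),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return _validate(raw)


def dump_config(cfg: ExperimentConfig, path: str | Path | None = None) -> str:
    """Serialise a resolved config to YAML; ``dump → load`` is the identity."""
    data = asdict(cfg)
    data["t_span"] = list(cfg.t_span)
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
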