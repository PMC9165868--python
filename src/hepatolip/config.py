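"""Run configuration: flat YAML schema, strict validation, unit conversion.

Unknown keys anywhere in a config are hard errors (with a nearest-name
suggestion), so typos never silently fall back to defaults.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dosing import DoseEvent
from .params import DimensionalParameters, Scales, default_parameters
from .simulate import Scenario
from .states import STATE_NAMES

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "convert_concentration",
    "AVOGADRO",
    "DEFAULT_MOLAR_MASS_KDA",
]

AVOGADRO = 6.02214076e23

#: PCSK9 molar mass convention making 1e12 molec./mL ~ 100 ng/mL.
DEFAULT_MOLAR_MASS_KDA = 60.0

_UNIT_ALIASES = {
    "molec./mL": "molec./mL",
    "molec/mL": "molec./mL",
    "molec.mL": "molec./mL",
    "ng/mL": "ng/mL",
}


class ConfigError(ValueError):
    """Schema violation in a config file."""


def convert_concentration(
    value: float,
    from_units: str,
    to_units: str,
    molar_mass_kDa: float = DEFAULT_MOLAR_MASS_KDA,
) -> float:
    """Convert between number concentration (molec./mL) and mass concentration
    (ng/mL) via Avogadro's number; exact round trip."""
    try:
        src = _UNIT_ALIASES[from_units]
        dst = _UNIT_ALIASES[to_units]
    except KeyError as err:
        raise ConfigError(
            f"unknown concentration units {err.args[0]!r}; "
            f"expected one of {sorted(set(_UNIT_ALIASES.values()))}"
        ) from None
    if not (molar_mass_kDa > 0):
        raise ConfigError(f"molar mass must be positive, got {molar_mass_kDa!r}")
    if src == dst:
        return float(value)
    ng_per_molecule = molar_mass_kDa * 1e3 / AVOGADRO * 1e9
    if src == "molec./mL":  # -> ng/mL
        return float(value) * ng_per_molecule
    return float(value) / ng_per_molecule


def _reject_unknown(given: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        hints = []
        for key in sorted(unknown):
            close = difflib.get_close_matches(key, allowed, n=1)
            hints.append(f"{key!r}" + (f" (did you mean {close[0]!r}?)" if close else ""))
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(hints)}")


_SCENARIO_KEYS = {
    "initial", "events", "horizon_h", "output_step_h", "output_times_h",
}
_SOLVER_KEYS = {"method", "rtol", "atol", "max_step_s"}
_EVENT_KEYS = {
    "time_h", "species", "mode", "amount", "duration_h", "units",
    "molar_mass_kDa",
}
_TOP_KEYS = {
    "scenario", "parameters", "solver", "output_dir", "verbosity", "seed",
}

_PARAM_NAMES = (
    {f.name for f in fields(DimensionalParameters)} - {"scales"}
) | {f.name for f in fields(Scales)}


@dataclass
class RunConfig:
    """Validated run configuration (defaults-only when built from an empty file)."""

    scenario_name: str | None = None
    initial: dict[str, float] = field(default_factory=dict)
    events: tuple[DoseEvent, ...] = ()
    horizon_h: float = 200.0
    output_step_h: float = 0.5
    output_times_h: tuple[float, ...] | None = None
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    solver: dict[str, Any] = field(default_factory=dict)
    output_dir: str = "hepatolip_out"
    verbosity: str = "info"
    seed: int = 0

    def parameters(self) -> DimensionalParameters:
        return default_parameters(**self.parameter_overrides)

    def build_scenario(self) -> Scenario:
        """Inline scenario -> Scenario (preset names resolve in the CLI layer)."""
        return Scenario.from_concentrations(
            self.parameters(),
            self.initial,
            events=self.events,
            horizon_h=self.horizon_h,
            output_step_h=self.output_step_h,
            output_times_h=self.output_times_h,
            **self.solver,
        )


def _parse_event(rec: Mapping[str, Any], i: int) -> DoseEvent:
    if not isinstance(rec, Mapping):
        raise ConfigError(f"event #{i} must be a mapping, got {type(rec).__name__}")
    _reject_unknown(rec, _EVENT_KEYS, f"event #{i}")
    amount = float(rec.get("amount", 0.0))
    units = rec.get("units", "molec./mL")
    if units != "molec./mL":
        amount = convert_concentration(
            amount, units, "molec./mL",
            molar_mass_kDa=float(rec.get("molar_mass_kDa", DEFAULT_MOLAR_MASS_KDA)),
        )
    return DoseEvent(
        time_h=float(rec.get("time_h", 0.0)),
        species=str(rec.get("species", "")),
        mode=str(rec.get("mode", "bolus")),
        amount=amount,
        duration_h=float(rec.get("duration_h", 0.0)),
    )


def parse_config(data: Mapping[str, Any] | None, where: str = "config") -> RunConfig:
    data = data or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{where} root must be a mapping")
    _reject_unknown(data, _TOP_KEYS, where)
    cfg = RunConfig()

    scen = data.get("scenario", {})
    if isinstance(scen, str):
        cfg.scenario_name = scen
        scen = {}
    if not isinstance(scen, Mapping):
        raise ConfigError("'scenario' must be a mapping or a preset name")
    _reject_unknown(scen, _SCENARIO_KEYS, "scenario")
    initial = dict(scen.get("initial") or {})
    _reject_unknown(initial, set(STATE_NAMES), "scenario.initial")
    cfg.initial = {k: float(v) for k, v in initial.items()}
    cfg.events = tuple(
        _parse_event(rec, i) for i, rec in enumerate(scen.get("events") or [])
    )
    cfg.horizon_h = float(scen.get("horizon_h", cfg.horizon_h))
    cfg.output_step_h = float(scen.get("output_step_h", cfg.output_step_h))
    if scen.get("output_times_h") is not None:
        cfg.output_times_h = tuple(float(t) for t in scen["output_times_h"])

    overrides = dict(data.get("parameters") or {})
    _reject_unknown(overrides, _PARAM_NAMES, "parameters")
    cfg.parameter_overrides = {k: float(v) for k, v in overrides.items()}

    solver = dict(data.get("solver") or {})
    _reject_unknown(solver, _SOLVER_KEYS, "solver")
    cfg.solver = solver

    cfg.output_dir = str(data.get("output_dir", cfg.output_dir))
    cfg.verbosity = str(data.get("verbosity", cfg.verbosity)).lower()
    if cfg.verbosity not in ("debug", "info", "warning", "error"):
        raise ConfigError(f"unknown verbosity {cfg.verbosity!r}")
    cfg.seed = int(data.get("seed", cfg.seed))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; an empty file yields defaults."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    return parse_config(data, where=str(path))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a config so that load(save(cfg)) round-trips exactly."""
    data: dict[str, Any] = {
        "scenario": {
            "initial": cfg.initial,
            "events": [
                {
                    "time_h": e.time_h, "species": e.species, "mode": e.mode,
                    "amount": e.amount, "duration_h": e.duration_h,
                }
                for e in cfg.events
            ],
            "horizon_h": cfg.horizon_h,
            "output_step_h": cfg.output_step_h,
            "output_times_h": (
                list(cfg.output_times_h) if cfg.output_times_h is not None else None
            ),
        },
        "parameters": cfg.parameter_overrides,
        "solver": cfg.solver,
        "output_dir": cfg.output_dir,
        "verbosity": cfg.verbosity,
        "seed": cfg.seed,
    }
    if cfg.scenario_name is not None:
        data["scenario"] = cfg.scenario_name
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
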