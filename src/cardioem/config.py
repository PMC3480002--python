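"""Run configuration: defaulted, unit-checked, YAML round-trippable.

A run configuration is a single YAML document with one block per module
(``geometry``, ``ionic``, ``tension``, ``material``, ``solver``) plus a few
top-level scalars.  Every field has the published default, so the empty
document is a valid configuration.  Unknown keys are rejected with typed,
per-field error messages, and all validation failures are enumerated before
any compute starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Tuple

import yaml

from .active_tension import ActiveTensionParams
from .continuum import MaterialParams
from .errors import ConfigError
from .fem import SolverConfig
from .geometry import GeometrySpec, ScarSpec, StimulusSpec
from .ionic import IonicParams


@dataclass
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    ionic: IonicParams = field(default_factory=IonicParams)
    tension: ActiveTensionParams = field(default_factory=ActiveTensionParams)
    material: MaterialParams = field(default_factory=MaterialParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    duration: float = 20.0            # ms
    output_interval: float = 1.0      # ms
    probes: List[Tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0                     # reserved; the model is deterministic
    mode: str = "coupled"             # "coupled" | "ep_only"


_BLOCKS = {
    "geometry": GeometrySpec,
    "ionic": IonicParams,
    "tension": ActiveTensionParams,
    "material": MaterialParams,
    "solver": SolverConfig,
}

_NESTED = {"stimulus": StimulusSpec, "scar": ScarSpec}


def _coerce(value, default, path, errors):
    """Coerce a raw YAML value to the type of the field default."""
    try:
        if default is None:
            if value is None:
                return None
            if isinstance(value, (list, tuple)):
                return tuple(float(x) for x in value)
            return value
        if isinstance(default, bool):
            return bool(value)
        if isinstance(default, int) and not isinstance(default, bool):
            if isinstance(value, float) and value != int(value):
                errors.append(f"{path}: expected integer, got {value!r}")
                return default
            return int(value)
        if isinstance(default, float):
            return float(value)
        if isinstance(default, tuple):
            return tuple(float(x) for x in value)
        if isinstance(default, str):
            return str(value)
    except (TypeError, ValueError):
        errors.append(f"{path}: cannot interpret {value!r}")
        return default
    return value


def _build(cls, raw, path, errors):
    """Instantiate dataclass ``cls`` from a raw mapping, rejecting unknown keys."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        errors.append(f"{path}: expected a mapping, got {type(raw).__name__}")
        return cls()
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            errors.append(f"{path}.{key}: unknown key")
            continue
        if key in _NESTED:
            if value is None:
                kwargs[key] = None
            else:
                kwargs[key] = _build(_NESTED[key], value, f"{path}.{key}", errors)
            continue
        proto = cls()
        kwargs[key] = _coerce(value, getattr(proto, key), f"{path}.{key}", errors)
    return cls(**kwargs)


def validate_config(raw) -> RunConfig:
    """Build a fully defaulted :class:`RunConfig` from a raw mapping.

    Raises :class:`ConfigError` listing every offending field.
    """
    errors: list[str] = []
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration must be a mapping, got {type(raw).__name__}")

    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in top_known:
            errors.append(f"{key}: unknown key")

    blocks = {}
    for name, cls in _BLOCKS.items():
        blocks[name] = _build(cls, raw.get(name), name, errors)

    cfg = RunConfig(**blocks)
    if "duration" in raw:
        cfg.duration = _coerce(raw["duration"], 1.0, "duration", errors)
    if "output_interval" in raw:
        cfg.output_interval = _coerce(raw["output_interval"], 1.0,
                                      "output_interval", errors)
    if "seed" in raw:
        cfg.seed = _coerce(raw["seed"], 0, "seed", errors)
    if "mode" in raw:
        cfg.mode = str(raw["mode"])
    if "probes" in raw:
        try:
            cfg.probes = [tuple(float(c) for c in p) for p in raw["probes"]]
            if any(len(p) != 3 for p in cfg.probes):
                errors.append("probes: each probe must be a 3-coordinate point")
        except (TypeError, ValueError):
            errors.append(f"probes: cannot interpret {raw['probes']!r}")

    # cross-field invariants
    if cfg.duration < 0:
        errors.append(f"duration must be >= 0, got {cfg.duration}")
    if cfg.output_interval < cfg.solver.dt_pde:
        errors.append(
            f"output_interval ({cfg.output_interval}) must be >= solver.dt_pde "
            f"({cfg.solver.dt_pde})")
    if cfg.mode not in ("coupled", "ep_only"):
        errors.append(f"mode must be 'coupled' or 'ep_only', got {cfg.mode!r}")
    errors.extend(cfg.geometry.validate())
    errors.extend(cfg.ionic.validate())
    errors.extend(cfg.tension.validate())
    errors.extend(cfg.material.validate())
    errors.extend(cfg.solver.validate())

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict (YAML-serializable) view of a configuration."""
    d = dataclasses.asdict(cfg)

    def tuples_to_lists(obj):
        if isinstance(obj, dict):
            return {k: tuples_to_lists(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [tuples_to_lists(v) for v in obj]
        return obj

    return tuples_to_lists(d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def save_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
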