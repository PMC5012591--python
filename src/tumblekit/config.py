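"""Flat key-value run configuration.

Format: one ``key = value`` pair per line; ``#`` starts a comment; keys
are dotted paths into parameter groups::

    seed = 1
    n_cells = 200
    duration = 120
    tb = 0.2                 # or: yp = 2.75 (uM)
    out_dir = runs/demo

    motor.epsilon = 1.3
    motor.g = 40
    motor.K_D = 3.06
    swim.speed = 20
    swim.D_rot = 0.062
    swim.depth = 10
    swim.dt_sample = 0.1
    swim.dt_internal = 0.01
    swim.loc_noise = 0.1
    pathway.k_R = 0.12
    noise.eta_int = 0.125
    noise.eta_ext = 0.26

Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .noise import NoiseSpec
from .pathway import PathwayParams
from .simulate import MotorParams, SwimParams

__all__ = ["RunConfig", "load_config", "parse_config_text", "ConfigError"]


class ConfigError(ValueError):
    """Malformed or unknown configuration key/value."""


_TOP_KEYS = {
    "seed": int,
    "n_cells": int,
    "duration": float,
    "yp": float,
    "tb": float,
    "out_dir": str,
    "min_duration": float,
    "tol": float,
    "max_lag": float,
    "bandwidth": float,
    "with_lna": lambda s: s.lower() in ("1", "true", "yes"),
    "verbosity": int,
}

_GROUPS = {
    "motor": MotorParams,
    "swim": SwimParams,
    "pathway": PathwayParams,
    "noise": NoiseSpec,
}


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int = 0
    n_cells: int = 100
    duration: float = 120.0
    yp: Optional[float] = None
    tb: Optional[float] = None
    out_dir: str = "runs/out"
    min_duration: float = 10.0
    tol: float = 0.01
    max_lag: Optional[float] = None
    bandwidth: float = 0.2
    with_lna: bool = True
    verbosity: int = 1
    motor: MotorParams = field(default_factory=MotorParams)
    swim: SwimParams = field(default_factory=SwimParams)
    pathway: PathwayParams = field(default_factory=PathwayParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)


def _coerce(cls, name: str, raw: str):
    f = {fl.name: fl for fl in dataclasses.fields(cls)}.get(name)
    if f is None:
        raise ConfigError(f"unknown key {cls.__name__}.{name}")
    if f.type in ("int", int):
        return int(raw)
    if f.type in ("bool", bool):
        return raw.lower() in ("1", "true", "yes")
    try:
        return float(raw)
    except ValueError as err:
        raise ConfigError(f"cannot parse value {raw!r} for {name}") from err


def parse_config_text(text: str) -> RunConfig:
    top: dict = {}
    group_overrides: dict[str, dict] = {g: {} for g in _GROUPS}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        if "." in key:
            group, sub = key.split(".", 1)
            if group not in _GROUPS:
                raise ConfigError(f"line {lineno}: unknown group {group!r}")
            group_overrides[group][sub] = _coerce(_GROUPS[group], sub, raw)
        else:
            if key not in _TOP_KEYS:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            top[key] = _TOP_KEYS[key](raw)

    cfg = RunConfig(**top)
    for group, overrides in group_overrides.items():
        if overrides:
            base = getattr(cfg, group)
            if group == "noise":
                setattr(cfg, group, dataclasses.replace(base, **overrides))
            else:
                setattr(cfg, group, dataclasses.replace(base, **overrides))
    return cfg


def load_config(path) -> RunConfig:
    return parse_config_text(Path(path).read_text())
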