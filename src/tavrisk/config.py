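"""Run configuration: one YAML file governs all pipeline stages.

Defaults match the shipped model constants (material table, 7820-element mesh,
90 deg conduction sector, 0.6 mm AV-bundle radius, nominal sizes 23/26/29/31).
Unknown keys are rejected loudly; ``load_config(save_config(c)) == c``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, get_args, get_origin, get_type_hints

import yaml

from .cohort import GeneratorParams, GroundTruthModel, TruncNormal

__all__ = [
    "MaterialConfig",
    "MeshConfig",
    "ModelConfig",
    "OptimizerConfig",
    "RunConfig",
    "default_config",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class MaterialConfig:
    root_youngs_modulus: float = 2.0  # MPa
    root_poisson_ratio: float = 0.45
    root_density: float = 2000.0  # kg/m^3
    valve_youngs_modulus: float = 8.0
    valve_poisson_ratio: float = 0.45
    valve_density: float = 1100.0
    wall_stiffness: float = 10.0  # N/mm (force-displacement regression input)


@dataclass(frozen=True)
class MeshConfig:
    resolution: tuple[int, int, int] = (92, 17, 5)  # 7820 hexahedra
    band_height: float = 4.0  # mm, conduction-zone axial band
    half_angle_deg: float = 45.0  # 90 deg sector total
    av_bundle_radius: float = 0.6  # mm


@dataclass(frozen=True)
class ModelConfig:
    threshold: float = 0.5
    epsilon: float = 0.01
    select_k: int = 16
    lam: float | None = None  # None -> inner 5-fold CV over the log grid


@dataclass(frozen=True)
class OptimizerConfig:
    sizes: tuple[float, ...] = (23.0, 26.0, 29.0, 31.0)
    theta_max_deg: float = 15.0
    theta_step_deg: float = 1.0
    target_risk: float = 0.0
    oversize_ratio: float = 1.15


@dataclass(frozen=True)
class RunConfig:
    materials: MaterialConfig = field(default_factory=MaterialConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    seed: int = 0


def default_config() -> RunConfig:
    return RunConfig()


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: Any):
    if is_dataclass(cls):
        if not isinstance(data, dict):
            raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
        hints = get_type_hints(cls)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in section {cls.__name__}"
            )
        kwargs = {}
        for f in fields(cls):
            if f.name in data:
                kwargs[f.name] = _coerce(hints[f.name], data[f.name])
        return cls(**kwargs)
    raise TypeError(f"{cls} is not a dataclass")


def _coerce(hint, value):
    origin = get_origin(hint)
    if origin is tuple:
        args = get_args(hint)
        if len(args) == 2 and args[1] is Ellipsis:
            return tuple(_coerce(args[0], v) for v in value)
        return tuple(_coerce(a, v) for a, v in zip(args, value))
    if origin is not None and str(origin) in ("typing.Union", str(type(None) | int)):
        pass
    # optional floats (lam) arrive as None or number
    if hint in (float, "float"):
        return float(value)
    if hint in (int, "int"):
        return int(value)
    if is_dataclass(hint):
        return _from_plain(hint, value)
    # unions like float | None
    args = get_args(hint)
    if args:
        if value is None and type(None) in args:
            return None
        for a in args:
            if a is not type(None):
                try:
                    return _coerce(a, value)
                except (TypeError, ValueError):
                    continue
    return value


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)
    return path


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _from_plain(RunConfig, data)
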