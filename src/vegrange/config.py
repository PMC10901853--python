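"""Run configuration: one YAML schema covering every module parameter block.

A run is fully replayable from its emitted resolved config: every default is
materialised on load, unknown keys are rejected with the offending key named,
and all values validate before any computation starts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import vegetation as vg
from .carbon import CarbonParams, CouplerConfig, ModelParams
from .ensemble import EnsembleSpec
from .weathering import WeatheringParams
from .worlds import (ClimateField, ClimateParams, ForcingState, WorldGrid,
                     load_climate, make_dispersed, make_grid, make_supercontinent)

__all__ = ["ConfigError", "WorldSpec", "RunConfig", "load_config", "dump_config",
           "build_world", "build_model_params"]


class ConfigError(ValueError):
    """Malformed run configuration (unknown key, bad value, bad type)."""


def _build(cls, data: dict | None, section: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    data = dict(data or {})
    names = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in names:
            raise ConfigError(f"unknown key '{key}' in section '{section}'")
    # YAML has no tuples; coerce lists where the default is a tuple
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


@dataclass
class WorldSpec:
    """World source: a named generator or an input climate file."""

    generator: str = "dispersed"  # supercontinent | dispersed | file
    n_lat: int = 40
    n_lon: int = 48
    land_fraction: float = 0.30
    n_blocks: int = 4
    center_lat: float = 0.0
    basalt_fraction: float = 0.25
    path: str | None = None
    seed: int | None = None  # falls back to the run seed

    def __post_init__(self) -> None:
        if self.generator not in ("supercontinent", "dispersed", "file"):
            raise ValueError(f"unknown world generator '{self.generator}'")
        if self.generator == "file" and not self.path:
            raise ValueError("world generator 'file' requires a path")


@dataclass
class RunConfig:
    """Resolved configuration of a single experiment."""

    seed: int = 0
    output_dir: str = "runs/latest"
    world: WorldSpec = field(default_factory=WorldSpec)
    forcing: ForcingState = field(default_factory=ForcingState)
    climate: ClimateParams = field(default_factory=ClimateParams)
    photosynthesis: vg.PhotosynthesisParams = field(default_factory=vg.PhotosynthesisParams)
    pfts: dict = field(default_factory=lambda: dict(vg.DEFAULT_PFTS))
    weathering: WeatheringParams = field(default_factory=WeatheringParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    coupler: CouplerConfig = field(default_factory=CouplerConfig)
    ensemble: EnsembleSpec | None = None
    compare: dict[str, WorldSpec] | None = None  # keys world_a, world_b


_SECTIONS = ("world", "forcing", "climate", "photosynthesis", "pfts",
             "weathering", "carbon", "coupler", "ensemble", "compare")
_SCALARS = ("seed", "output_dir")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, filling in every default."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    for key in raw:
        if key not in _SECTIONS and key not in _SCALARS:
            raise ConfigError(f"unknown top-level key '{key}'")
    pfts = dict(vg.DEFAULT_PFTS)
    for name, ramp in (raw.get("pfts") or {}).items():
        if name not in pfts:
            raise ConfigError(f"unknown PFT '{name}' in section 'pfts'")
        if not (isinstance(ramp, (list, tuple)) and len(ramp) == 4):
            raise ConfigError(f"PFT '{name}' needs [t_min, t_opt_lo, t_opt_hi, t_max]")
        try:
            pfts[name] = vg.PFTParams(name, *map(float, ramp))
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    ens = raw.get("ensemble")
    compare = raw.get("compare")
    if compare is not None:
        if set(compare) != {"world_a", "world_b"}:
            raise ConfigError("section 'compare' needs exactly world_a and world_b")
        compare = {k: _build(WorldSpec, v, f"compare.{k}") for k, v in compare.items()}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "runs/latest")),
        world=_build(WorldSpec, raw.get("world"), "world"),
        forcing=_build(ForcingState, raw.get("forcing"), "forcing"),
        climate=_build(ClimateParams, raw.get("climate"), "climate"),
        photosynthesis=_build(vg.PhotosynthesisParams, raw.get("photosynthesis"),
                              "photosynthesis"),
        pfts=pfts,
        weathering=_build(WeatheringParams, raw.get("weathering"), "weathering"),
        carbon=_build(CarbonParams, raw.get("carbon"), "carbon"),
        coupler=_build(CouplerConfig, raw.get("coupler"), "coupler"),
        ensemble=_build(EnsembleSpec, ens, "ensemble") if ens is not None else None,
        compare=compare,
    )


def _plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN has no portable YAML form
        return None
    return obj


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config so the run can be replayed exactly."""
    data = _plain(config)
    # PFTParams carry their name as the mapping key already
    data["pfts"] = {name: [p.t_min, p.t_opt_lo, p.t_opt_hi, p.t_max]
                    for name, p in config.pfts.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def build_world(spec: WorldSpec, default_seed: int = 0,
                time_Ma: float = 0.0) -> tuple[WorldGrid, ClimateField | None]:
    """Realise a WorldSpec: (grid, climate-from-file-or-None)."""
    seed = default_seed if spec.seed is None else spec.seed
    if spec.generator == "file":
        return load_climate(spec.path, time_Ma=time_Ma)
    grid = make_grid(spec.n_lat, spec.n_lon)
    if spec.generator == "supercontinent":
        return make_supercontinent(grid, spec.land_fraction, spec.center_lat,
                                   seed, spec.basalt_fraction), None
    return make_dispersed(grid, spec.land_fraction, spec.n_blocks, seed,
                          spec.basalt_fraction), None


def build_model_params(config: RunConfig) -> ModelParams:
    return ModelParams(
        photosynthesis=config.photosynthesis,
        pfts=config.pfts,
        climate=config.climate,
        weathering=config.weathering,
        carbon=config.carbon,
    )
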