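"""YAML run configuration: strict validation, resolved-config provenance.

A config file may override any subset of the known sections; unknown keys are
rejected so that typos fail loudly.  Every CLI run writes the fully resolved
configuration next to its outputs, making runs reproducible from
(inputs, resolved config, seed) alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionParams
from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class MetricOptions:
    match_radius_px: float = 25.0  # about half the nominal plant spacing in pixels
    round_digits: int = 2
    fit_gamma: bool = True


@dataclass(frozen=True)
class SimulationOptions:
    rows: int = 15
    cols: int = 15
    pd: float = 3.0
    rd: float = 2.0
    replicates: int = 100
    sigma1: float = 0.0
    sigma2: float = 0.0
    p: float = 0.0
    n: int = 225


@dataclass(frozen=True)
class SceneOptions:
    width: int = 900
    height: int = 900
    gsd: float = 0.2
    blades_per_cluster: int = 5
    blade_length: int = 18
    bubble_density: float = 20.0
    speckle_density: float = 300.0


@dataclass(frozen=True)
class RunConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    metrics: MetricOptions = field(default_factory=MetricOptions)
    simulation: SimulationOptions = field(default_factory=SimulationOptions)
    scene: SceneOptions = field(default_factory=SceneOptions)
    gsd: float | None = None
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"


_SECTIONS = {
    "detection": DetectionParams,
    "metrics": MetricOptions,
    "simulation": SimulationOptions,
    "scene": SceneOptions,
}
_SCALARS = {"gsd", "seed", "output_dir", "log_level"}


def _build_section(cls, data, name: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values in '{name}': {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus programmatic overrides."""
    data: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
        except OSError:
            raise
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = (
                data[name] if isinstance(data[name], cls) else _build_section(cls, data[name], name)
            )
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration (run provenance)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
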