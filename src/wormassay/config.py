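"""Declarative analysis configuration.

One YAML file holds every tunable: kinematic thresholds (in internal
units, mm and s), pirouette-detector settings, plate geometry, and
statistics options.  ``load_config`` resolves the file over the package
defaults and logs the fully-resolved configuration so every run is
replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError
from .trackio import PlateGeometry

logger = logging.getLogger("wormassay")


@dataclass
class KinematicsConfig:
    immobility_threshold: float = 0.2  # mm/s (0.02 cm/s)
    max_speed: float = 0.5             # mm/s (500 um/s tracker ceiling)
    smoothing_window: int = 0          # frames; 0 disables the moving average


@dataclass
class PirouetteConfig:
    window: float = 3.0            # s
    angle_threshold: float = 120.0  # degrees
    drop_threshold: float = 0.40   # fraction
    baseline: float = 2.0          # s
    min_step: float = 0.01         # mm displacement floor for headings
    resample_dt: float = 0.5       # s heading timebase (0 -> per-frame)
    merge_gap: float = 1.0         # s refractory merge
    mode: str = "net"              # net | absolute cumulative turning


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_boot: int = 10000
    seed: int = 0


@dataclass
class AnalysisConfig:
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    pirouettes: PirouetteConfig = field(default_factory=PirouetteConfig)
    geometry: PlateGeometry = field(default_factory=PlateGeometry)
    stats: StatsConfig = field(default_factory=StatsConfig)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an AnalysisConfig, overlaying a YAML file (if given) on the
    defaults, and log the fully-resolved configuration."""
    cfg = AnalysisConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        for section, target in (("kinematics", cfg.kinematics),
                                ("pirouettes", cfg.pirouettes),
                                ("stats", cfg.stats)):
            for key, val in (data.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ConfigError(f"{path}: unknown key {section}.{key}")
                setattr(target, key, val)
        if "geometry" in data:
            try:
                cfg.geometry = PlateGeometry(**data["geometry"])
            except TypeError as exc:
                raise ConfigError(f"{path}: bad geometry section: {exc}") from None
    logger.info("resolved config: %s", resolved_config(cfg))
    return cfg


def resolved_config(cfg: AnalysisConfig) -> dict:
    """The fully-resolved configuration as a plain dict (for logging)."""
    return asdict(cfg)
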