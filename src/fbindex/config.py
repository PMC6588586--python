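"""Structured monitor configuration.

Every threshold that is a package convention rather than a published value
(active-speed threshold, turn angle, wall margin, occupancy grid, score
truncation) is a named key here, so an audit of conventions is one file.
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .features import FeatureConfig
from .trajectory_io import TankGeometry

__all__ = ["MonitorConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid monitor configuration."""


@dataclass(frozen=True)
class MonitorConfig:
    """Full configuration of the monitoring pipeline."""

    tank: TankGeometry = field(default_factory=TankGeometry)
    rate_hz: float = 25.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    dev_max: float = 1.0
    windows: tuple[int, ...] = (1, 10, 20, 30)
    coverage_floor: float = 0.5
    alert_window: int = 10
    max_gap_s: float = 2.0
    # category table as (upper score edge, label), ascending, last edge 6.0
    category_bins: tuple[tuple[float, str], ...] = (
        (2.0, "Abnormal"), (4.0, "Unhealthy"), (5.0, "Ok"), (6.0, "Healthy"),
    )
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.dev_max <= 0:
            raise ConfigError("dev_max must be positive")
        if not (0 < self.coverage_floor <= 1):
            raise ConfigError("coverage_floor must lie in (0, 1]")
        if self.alert_window not in self.windows:
            raise ConfigError("alert_window must be one of the configured windows")
        for thr in ("active_speed_cms", "turn_threshold_deg", "fast_speed_cms",
                    "sharp_angle_deg", "wall_margin_frac"):
            if getattr(self.features, thr) <= 0:
                raise ConfigError(f"feature threshold {thr} must be positive")
        edges = [e for e, _ in self.category_bins]
        if edges != sorted(edges) or len(set(edges)) != len(edges):
            raise ConfigError("category bin edges must be strictly increasing")
        if edges[-1] != 6.0:
            raise ConfigError("category bins leave a gap in [0, 6]: last edge must be 6.0")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["tank"] = asdict(self.tank)
        d["features"] = asdict(self.features)
        d["windows"] = list(self.windows)
        d["category_bins"] = [[float(e), lab] for e, lab in self.category_bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MonitorConfig":
        d = dict(d)
        if "tank" in d:
            d["tank"] = TankGeometry(**d["tank"])
        if "features" in d:
            d["features"] = FeatureConfig(**d["features"])
        if "windows" in d:
            d["windows"] = tuple(int(w) for w in d["windows"])
        if "category_bins" in d:
            d["category_bins"] = tuple((float(e), str(lab)) for e, lab in d["category_bins"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MonitorConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)
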