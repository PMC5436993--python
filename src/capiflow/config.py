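"""Run configuration: a validated YAML block per pipeline stage.

Unknown keys are rejected so that typos in a config file fail loudly
instead of silently running with defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .framestack import Calibration

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _from_mapping(cls, mapping: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class VesselsConfig:
    min_diameter_um: float = 4.0
    max_diameter_um: float = 30.0
    n_scales: int = 8
    beta: float = 0.5
    c: float | None = None
    threshold: float = 0.15
    min_length_um: float = 10.0
    min_area_px: int = 30


@dataclass(frozen=True)
class VelocimetryConfig:
    kernel_sigma_px: float = 2.0
    perfusion_factor: float = 2.0


@dataclass(frozen=True)
class QualityConfig:
    clip_frac_good: float = 0.01
    clip_frac_marginal: float = 0.05
    focus_good: float = 0.02
    focus_marginal: float = 0.005
    step_good_px: float = 2.0
    step_marginal_px: float = 4.0
    duration_good: int = 150
    duration_marginal: int = 75
    overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WindowConfig:
    min_frames: int = 150
    max_step_px: float = 2.0
    max_span_px: float = 10.0


@dataclass(frozen=True)
class StatsConfig:
    pairwise_test: str = "welch"  # or "ranksum"


@dataclass(frozen=True)
class RunConfig:
    calibration: Calibration
    vessels: VesselsConfig = VesselsConfig()
    velocimetry: VelocimetryConfig = VelocimetryConfig()
    quality: QualityConfig = QualityConfig()
    window: WindowConfig = WindowConfig()
    stats: StatsConfig = StatsConfig()
    output_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        known = {"calibration", "vessels", "velocimetry", "quality", "window",
                 "stats", "output_dir", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        if "calibration" not in raw:
            raise ConfigError("config requires a 'calibration' block (no silent default pitch)")
        try:
            calibration = Calibration.from_mapping(raw["calibration"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid calibration block: {exc}") from exc
        return cls(
            calibration=calibration,
            vessels=_from_mapping(VesselsConfig, raw.get("vessels", {}), "vessels"),
            velocimetry=_from_mapping(VelocimetryConfig, raw.get("velocimetry", {}), "velocimetry"),
            quality=_from_mapping(QualityConfig, raw.get("quality", {}), "quality"),
            window=_from_mapping(WindowConfig, raw.get("window", {}), "window"),
            stats=_from_mapping(StatsConfig, raw.get("stats", {}), "stats"),
            output_dir=raw.get("output_dir", "."),
            seed=int(raw.get("seed", 0)),
        )

    def content_hash(self) -> str:
        """Short stable hash of the configuration (written into outputs)."""

        def enc(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)}
            return obj

        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
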