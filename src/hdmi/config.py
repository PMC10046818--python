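"""Pipeline configuration: defaults, JSON round-trip, and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["FormationConfig", "EnhancementConfig", "GraphConfig",
           "MorphometricsConfig", "StatsConfig", "PipelineConfig"]


@dataclass
class FormationConfig:
    rank_cutoff: int = 2
    high_cutoff: int | None = None
    denoise_method: str = "noise_floor_subtraction"
    denoise_param: float = 0.5


@dataclass
class EnhancementConfig:
    scales: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0])
    threshold_method: str = "otsu_hysteresis"
    threshold: float = 0.5
    min_object_px: int = 30
    closing_radius: int = 1


@dataclass
class GraphConfig:
    min_spur_px: int = 5


@dataclass
class MorphometricsConfig:
    angle_probe_px: float = 20.0
    center_area_fraction: float = 0.5
    boundary_correction_px: float = 0.5


@dataclass
class StatsConfig:
    alpha: float = 0.05
    train_fraction: float = 0.7
    cv_folds: int = 5
    screen_on: str = "full"
    clinical: list[str] = field(default_factory=list)


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PipelineConfig:
    """All stage parameters plus global pixel size, seed and output dir.

    Serializes losslessly to JSON; unknown keys are rejected on load so a
    typo cannot silently fall back to a default.
    """

    pixel_size: float = 40.0
    seed: int = 0
    out_dir: str = "hdmi_out"
    formation: FormationConfig = field(default_factory=FormationConfig)
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    morphometrics: MorphometricsConfig = field(default_factory=MorphometricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "formation": FormationConfig,
            "enhancement": EnhancementConfig,
            "graph": GraphConfig,
            "morphometrics": MorphometricsConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                kwargs[key] = _from_dict(klass, d.pop(key))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON dump; changes iff a parameter does."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()
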