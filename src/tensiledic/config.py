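"""Run configuration: one document holding every tunable of the pipeline.

Loadable from YAML or JSON; every run's output embeds the fully resolved
configuration for provenance. Defaults follow the recommended protocol for
soft anisotropic specimens: 8.5 mm gauge length, 3 mm crack zone, 25 fps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dic import DicConfig
from .errors import InvalidArgumentError
from .geometry import SpecimenGeometry


@dataclass(frozen=True)
class ExtensometryConfig:
    crack_zone_length_mm: float = 3.0
    axial_strain_floor: float = 0.005
    sync_offset_s: float = 0.0
    idw_radius_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.crack_zone_length_mm <= 0:
            raise InvalidArgumentError("crack zone length must be positive")


@dataclass(frozen=True)
class MetricsConfig:
    drop_fraction: float = 0.3
    drop_window: int | None = None
    min_span_strain: float = 0.02
    r2_floor: float = 0.99
    include_descending: bool = False
    strain_source: str = "dic_gauge"  # machine | dic_gauge | dic_crack


@dataclass(frozen=True)
class RunConfig:
    geometry: SpecimenGeometry = field(
        default_factory=lambda: SpecimenGeometry(
            gauge_length_mm=8.5, gap_width_mm=20.0, width0_mm=10.0, thickness0_mm=4.0
        )
    )
    dic: DicConfig = field(default_factory=DicConfig)
    extensometry: ExtensometryConfig = field(default_factory=ExtensometryConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    pixel_scale: float = 0.05  # mm per px
    fps: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0 or self.fps <= 0:
            raise InvalidArgumentError("pixel_scale and fps must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs: dict = {}
        if "geometry" in doc:
            kwargs["geometry"] = SpecimenGeometry(**doc["geometry"])
        if "dic" in doc:
            kwargs["dic"] = DicConfig(**doc["dic"])
        if "extensometry" in doc:
            kwargs["extensometry"] = ExtensometryConfig(**doc["extensometry"])
        if "metrics" in doc:
            kwargs["metrics"] = MetricsConfig(**doc["metrics"])
        for key in ("pixel_scale", "fps", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(doc or {})

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
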