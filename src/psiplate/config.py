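"""Plate and hole design parameters with YAML loading.

Defaults: 2.0 mm plate thickness × 4.62 mm width, 0.5 mm section pitch,
6 mm boss discs around 2 mm screw holes with a 3.5 mm countersink head at
45°.  Everything is overridable from a YAML file or CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class HoleConfig:
    phi_mm: float = 2.0
    head_diameter_mm: float = 3.5
    head_angle_deg: float = 45.0
    segments: int = 64
    overshoot_mm: float = 0.2


@dataclass
class PlateConfig:
    thickness_mm: float = 2.0
    width_mm: float = 4.62
    sample_pitch_mm: float = 0.5
    boss_diameter_mm: float = 6.0
    screw_diameter_mm: float = 2.0
    q: int = 10
    smoothing: float = 0.99
    hole: HoleConfig = field(default_factory=HoleConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PlateConfig":
        data = dict(data or {})
        hole = HoleConfig(**data.pop("hole", {}))
        try:
            return cls(hole=hole, **data)
        except TypeError as exc:
            raise ParameterError(f"unknown config key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
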