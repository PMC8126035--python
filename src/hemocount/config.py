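"""Pipeline configuration: one JSON file drives every command."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    green_threshold: int = 200
    blue_threshold: int = 200
    window_radius: int = 2
    n_components: int = 10
    selected_pc: int | str = 4  # 1-based, or "auto"
    threshold_quantile: float = 0.05
    closing_radius: int = 1
    fill_holes: bool = True
    connectivity: int = 8
    filter_margin: float = 0.5
    alpha: float = 0.05
    pixel_size_um: float | None = None
    field_area_mm2: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("green_threshold", "blue_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValidationError(f"{name}={v} outside [0, 255]")
        if self.window_radius < 0:
            raise ValidationError("window_radius must be >= 0")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.selected_pc != "auto":
            if int(self.selected_pc) < 1 or int(self.selected_pc) > self.n_components:
                raise ValidationError(
                    f"selected_pc={self.selected_pc} outside 1..{self.n_components}"
                )
        if not (0.0 < self.threshold_quantile < 1.0):
            raise ValidationError("threshold_quantile must be in (0, 1)")
        if self.closing_radius < 0:
            raise ValidationError("closing_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if not (0.0 <= self.filter_margin < 1.0):
            raise ValidationError("filter_margin must be in [0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
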