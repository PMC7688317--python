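"""Pipeline configuration: one dataclass holding every tunable constant.

Defaults are the acquisition/analysis constants of the imaging protocol:
0.75 / 0.60 mm tile overlaps, 198 px (250 um) small patches, 8x8 merge
blocks with the 32-zero exclusion limit, and the 70%-of-the-top-1%
intensity threshold rule.  Configs load from YAML or JSON and serialise
back for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .phantom import DEFAULT_PIXEL_PITCH_UM

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # geometry
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    overlap_x_um: float = 750.0
    overlap_y_um: float = 600.0
    # N/C quantification
    patch_px: int = 198
    large_block: int = 8
    zero_limit: int = 32
    threshold_fraction: float = 0.70
    top_percent: float = 1.0
    edge_k: float = 2.0
    closing_radius: int = 3
    # preprocessing
    shading_sigma_frac: float = 0.125
    equalize_floor: float = 0.02
    # stitching
    search_radius_px: int = 8
    score_threshold: float = 0.3
    # phantom (desk-scale defaults; a real acquisition would be 2748x2200
    # px tiles — the analysis is size-agnostic, but tiles must exceed the
    # stage overlaps of 594x475 px at the default pitch)
    scene_width_px: int = 1260
    scene_height_px: int = 940
    tile_w_px: int = 760
    tile_h_px: int = 600
    vignette_strength: float = 0.3
    noise_sigma: float = 0.01
    phantom_classes: list = field(
        default_factory=lambda: ["IDC", "stroma", "adipose"]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "pixel_pitch_um", "overlap_x_um", "overlap_y_um", "patch_px",
            "large_block", "threshold_fraction", "top_percent", "edge_k",
            "shading_sigma_frac", "scene_width_px", "scene_height_px",
            "tile_w_px", "tile_h_px",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if not 0.0 < self.top_percent <= 100.0:
            raise ValueError("top_percent must lie in (0, 100]")
        if self.zero_limit < 0:
            raise ValueError("zero_limit must be nonnegative")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def overlap_px(self) -> tuple[int, int]:
        return (
            int(round(self.overlap_x_um / self.pixel_pitch_um)),
            int(round(self.overlap_y_um / self.pixel_pitch_um)),
        )
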