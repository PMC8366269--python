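"""Run configuration: every analysis parameter resolved to an explicit value."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class RunConfig(BaseModel):
    """Pipeline configuration with logged defaults.

    Any field not set in the config file keeps its documented default; the
    pipeline logs the fully resolved configuration so every analysis parameter
    is explicit in the run record.
    """

    input_dir: Path = Path(".")
    output_dir: Path = Path("out")

    # ABR cohort
    quartile_rule: str = "subject_mean"          # or per_frequency
    outside_fraction: float = 0.8
    percentile_method: str = "linear"            # interpolated order statistics
    no_response_policy: str = "ceiling"          # NR stored as 100 dB, in means
    ears: str = "average"                        # or per_ear

    # Cytocochleogram
    place_map_preset: str = "anchored_9khz"     # or muller2005
    scale_um_per_px: float = 1.0
    marker_max_distance_um: float = 200.0
    band_split_khz: float = 8.0
    weighted_band_mean: bool = False

    # Fluorescence quantification
    rolling_ball_radius: int = 6
    floor_threshold: int = 75
    eight_bit_mode: str = "full_scale"           # or display_range
    roi_circle_diameter_px: float = 100.0
    roi_rect_width_px: float = 100.0

    seed: int = 0

    type_map: dict[int, str] = Field(
        default_factory=lambda: {1: "OHC", 2: "OHx", 3: "IHC", 4: "IHx"})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved(self) -> dict:
        out = self.model_dump()
        out["input_dir"] = str(out["input_dir"])
        out["output_dir"] = str(out["output_dir"])
        return out
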