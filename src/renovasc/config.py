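"""Pipeline configuration.

Defaults carry the acquisition and processing constants of the study
design: 54 Hz frame rate, 600 s acquisition, 22.6 µm super-resolution
pixels, a 2 mm extraction slab, a 42.25 µm track diameter, and the
>1-detection-per-pixel inclusion threshold.  Scene-size parameters
(phantom grid, microbubble budget, cohort size) control how large a
synthetic run is and may be scaled down freely.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # acquisition / processing constants
    frame_rate_hz: float = 54.0
    duration_s: float = 600.0
    gate_mm: float = 0.28
    pixel_um: float = 22.6
    slab_width_mm: float = 2.0
    track_diameter_um: float = 42.25
    count_threshold: int = 1
    frc_threshold: str = "half-bit"
    # synthetic scene
    n_animals: int = 6
    phantom_semi_axes_mm: tuple[float, float, float] = (8.0, 5.0, 4.0)
    phantom_spacing_um: float = 250.0
    mb_budget: int = 12
    noise_sigma_mm: float = 0.005
    false_positive_rate: float = 0.5
    # cohort couplings
    r_map_hr: float = 0.5324
    slope_anaesthesia_yield: float = -0.004
    slope_map_yield: float = 0.004
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frame_rate_hz", "duration_s", "gate_mm", "pixel_um",
            "slab_width_mm", "track_diameter_um", "phantom_spacing_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.count_threshold < 0:
            raise ValueError("count_threshold must be nonnegative")
        self.phantom_semi_axes_mm = tuple(float(v) for v in self.phantom_semi_axes_mm)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["phantom_semi_axes_mm"] = list(d["phantom_semi_axes_mm"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "phantom_semi_axes_mm" in d:
            d["phantom_semi_axes_mm"] = tuple(d["phantom_semi_axes_mm"])
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
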