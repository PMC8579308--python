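"""Run configuration.

All lengths are µm.  Defaults follow the measurement geometry used in the
study this pipeline reproduces: a 3.3 µm sampling cylinder for the axial
fluorescence profile, a 30 µm oxic shell for viability and growth-ratio
measurements, growth-ratio query heights of 100 and 0 µm, and a competition
ring 35 µm wide at 350 µm from the inoculum edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # channel-role mapping: role -> index of channel in the input stack
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"stable_reporter": 0, "dead_stain": 1, "unstable_reporter": 2, "beads": 3}
    )
    # voxel calibration override (dx, dy, dz) µm; None = read from metadata
    voxel_size: tuple[float, float, float] | None = None
    # 'base_low' (canonical) or 'apex_low' (stack recorded facing down; flipped at ingestion)
    z_orientation: str = "base_low"

    # segmentation
    smooth_sigma_px: float = 1.0
    gradient_threshold: float | None = None  # None → per-slice Otsu
    min_slice_area_px: int = 50

    # spatial profiles
    shell_bin_um: float = 2.0
    cylinder_radius_um: float = 3.3
    surface_reference_um: float = 2.0
    include_base_as_surface: bool = False

    # viability / growth ratio
    oxic_shell_um: float = 30.0
    height_bin_um: float = 10.0
    threshold_rule: str = "otsu"  # or 'fixed'
    stable_threshold: float | None = None
    dead_threshold: float | None = None
    ratio_height_hi_um: float = 100.0
    ratio_height_lo_um: float = 0.0

    # competition ring
    ring_distance_um: float = 350.0
    ring_width_um: float = 35.0

    # morphology
    slope_query_height_um: float = 100.0
    slope_smooth_bins: int = 5

    # which analyses run_pipeline executes
    analyses: list[str] = field(
        default_factory=lambda: ["biovolume", "morphology", "shell", "axial", "basal", "viability", "ratio"]
    )

    seed: int = 0

    def __post_init__(self):
        if self.z_orientation not in ("base_low", "apex_low"):
            raise ValueError("z_orientation must be 'base_low' or 'apex_low'")
        if self.threshold_rule not in ("otsu", "fixed"):
            raise ValueError("threshold_rule must be 'otsu' or 'fixed'")
        for name in ("shell_bin_um", "oxic_shell_um", "height_bin_um", "ring_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.voxel_size is not None:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["voxel_size"] is not None:
            d["voxel_size"] = list(d["voxel_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
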