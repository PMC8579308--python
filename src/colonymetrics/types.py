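"""Core data containers shared by all analysis stages.

All physical quantities are in micrometres (µm) internally.  Arrays are
ordered ``(z, y, x)`` with the colony base (the filter-membrane side) at
z-index 0; voxel centres sit at ``(k + 0.5) * dz`` above the base plane.
Voxel-index quantities never cross module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


def _check_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 strictly positive values (dx, dy, dz), got {voxel_size!r}")
    return vs  # (dx, dy, dz)


@dataclass
class VoxelImage:
    """Calibrated multi-channel 3D intensity grid.

    Parameters
    ----------
    channels
        Mapping from channel role name to a 3D ``(z, y, x)`` float array.
        All channels must share one shape.
    voxel_size
        ``(dx, dy, dz)`` in µm.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.voxel_size = _check_voxel_size(self.voxel_size)
        if not self.channels:
            raise ValueError("VoxelImage needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share one shape, got {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise ValueError(f"channels must be 3D (z, y, x), got shape {shape}")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel role {name!r} not present; available: {sorted(self.channels)}"
            ) from None

    def flip_z(self) -> "VoxelImage":
        """Return a copy with the z axis reversed (apex-at-0 → base-at-0)."""
        return VoxelImage(
            {k: v[::-1].copy() for k, v in self.channels.items()}, self.voxel_size
        )


@dataclass
class ColonyMask:
    """Binary 3D occupancy of colony biomass, aligned to a :class:`VoxelImage`."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("ColonyMask must be 3D (z, y, x)")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class SurfaceDistanceMap:
    """Per-voxel Euclidean distance (µm) to the air-facing colony surface.

    ``data`` is NaN outside the colony mask; zero exactly on surface voxels.
    ``includes_base`` records whether voxels whose only exposure is to the
    substrate plane were treated as surface (off by default: oxygen arrives
    from the air, not through the filter).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    includes_base: bool = False

    def __post_init__(self):
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.data = np.asarray(self.data, dtype=np.float64)


@dataclass
class ShellProfile:
    """Mean intensity vs distance-to-surface, in fixed-width distance bins.

    Bins with zero voxels carry ``NaN`` means.  ``normalized`` intensities are
    relative to the outermost (surface) reference shell.
    """

    bin_center_um: np.ndarray
    mean_intensity: np.ndarray
    n_voxels: np.ndarray
    bin_width_um: float
    normalized: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "distance_um": self.bin_center_um,
            "mean_intensity_au": self.mean_intensity,
            "n_voxels": self.n_voxels,
        }
        if self.normalized is not None:
            d["normalized_intensity"] = self.normalized
        return pd.DataFrame(d)


@dataclass
class AxialProfile:
    """Mean intensity vs height within a thin vertical cylinder on the colony axis."""

    z_um: np.ndarray
    mean_intensity: np.ndarray
    normalized: np.ndarray
    reference_intensity: float
    cylinder_radius_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_um": self.z_um,
                "mean_intensity_au": self.mean_intensity,
                "normalized_intensity": self.normalized,
            }
        )


@dataclass
class HeightRadiusProfile:
    """Colony height h(r) vs radial distance from the colony axis."""

    r_um: np.ndarray
    h_um: np.ndarray
    center_xy_um: tuple[float, float]

    def __post_init__(self):
        self.r_um = np.asarray(self.r_um, dtype=np.float64)
        self.h_um = np.asarray(self.h_um, dtype=np.float64)
        if np.any(np.diff(self.r_um) <= 0):
            raise ValueError("radial coordinate must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.r_um, "height_um": self.h_um})


@dataclass
class MorphologyMetrics:
    """Scalar morphometric summary of a segmented colony."""

    height_um: float
    radius_um: float
    biovolume_um3: float
    slope_at_height: float | None = None
    slope_query_height_um: float | None = None

    def to_dict(self) -> dict:
        return {
            "height_um": self.height_um,
            "radius_um": self.radius_um,
            "biovolume_um3": self.biovolume_um3,
            "slope_at_height": self.slope_at_height,
            "slope_query_height_um": self.slope_query_height_um,
        }


@dataclass
class ViabilityProfile:
    """Dead-cell fraction per height bin, restricted to the oxic shell."""

    height_um: np.ndarray
    dead_fraction: np.ndarray
    n_voxels: np.ndarray
    shell_depth_um: float
    height_bin_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "height_um": self.height_um,
                "dead_fraction": self.dead_fraction,
                "n_voxels": self.n_voxels,
            }
        )


@dataclass
class CompetitionResult:
    """Strain ratio measured in an annulus around the inoculation spot."""

    ring_inner_um: float
    ring_outer_um: float
    fraction_strain1: float
    area1_um2: float
    area2_um2: float

    def to_dict(self) -> dict:
        return {
            "ring_inner_um": self.ring_inner_um,
            "ring_outer_um": self.ring_outer_um,
            "fraction_strain1": self.fraction_strain1,
            "area_strain1_um2": self.area1_um2,
            "area_strain2_um2": self.area2_um2,
        }
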