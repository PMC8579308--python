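"""Readers and writers: OME-TIFF stacks, CSV result tables, provenance JSON.

Stacks are stored as OME-TIFF with axes CZYX and physical voxel sizes in
the OME metadata; 8/16-bit integer and float stacks are accepted.  On
ingestion every stack is normalized to the canonical orientation with the
colony base (filter side) at z-index 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .types import VoxelImage

__all__ = ["read_stack", "write_stack", "write_table", "read_table", "write_provenance"]


def write_stack(image: VoxelImage, path: str | Path, channel_order: list[str] | None = None) -> None:
    """Write a :class:`VoxelImage` as a float32 OME-TIFF (axes CZYX)."""
    names = channel_order or list(image.channels)
    arr = np.stack([image.channel(n) for n in names]).astype(np.float32)
    dx, dy, dz = image.voxel_size
    tifffile.imwrite(
        str(path),
        arr,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def _voxel_size_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
        return (
            float(pixels["PhysicalSizeX"]),
            float(pixels["PhysicalSizeY"]),
            float(pixels["PhysicalSizeZ"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(path: str | Path, config: RunConfig) -> VoxelImage:
    """Read a multi-page TIFF / OME-TIFF into a canonical :class:`VoxelImage`.

    The voxel calibration comes from the OME metadata, or from
    ``config.voxel_size`` as an override; a stack with neither is an error,
    never a silent default.  Channels are mapped to roles through
    ``config.channel_roles`` (role → channel index) and the z axis is
    flipped when ``config.z_orientation == 'apex_low'``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        vs = _voxel_size_from_ome(tif)
    if config.voxel_size is not None:
        vs = tuple(config.voxel_size)
    if vs is None:
        raise ValueError(
            f"{path}: no voxel calibration in metadata and no config.voxel_size override"
        )
    if arr.ndim == 3:  # single channel ZYX
        arr = arr[None, ...]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a CZYX or ZYX stack, got shape {arr.shape}")
    # tifffile may return ZCYX for some writers; our writer produces CZYX
    n_ch = arr.shape[0]
    roles = config.channel_roles
    bad = [r for r, i in roles.items() if i >= n_ch]
    if bad:
        raise ValueError(
            f"{path}: config names channel roles {bad} but the stack has only {n_ch} channel(s)"
        )
    channels = {role: arr[idx].astype(np.float64) for role, idx in roles.items()}
    img = VoxelImage(channels, vs)
    if config.z_orientation == "apex_low":
        img = img.flip_z()
    return img


def write_table(records: pd.DataFrame | "object", path: str | Path) -> None:
    """Write a result table (or any object with ``to_frame``) as CSV.

    One header row; units are embedded in column names (``*_um``, ``*_au``).
    Numeric round-trip through :func:`read_table` is lossless to 1e-9
    relative.
    """
    if hasattr(records, "to_frame") and not isinstance(records, pd.DataFrame):
        records = records.to_frame()
    if not isinstance(records, pd.DataFrame):
        raise TypeError("records must be a DataFrame or expose to_frame()")
    records.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_provenance(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Record everything needed to reproduce a run: config, seed, version.

    Deliberately excludes wall-clock timestamps so identical runs produce
    byte-identical provenance.
    """
    from . import __version__

    record = {
        "software": "colonymetrics",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
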