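"""Distance-to-surface maps and fluorescence profiles.

The constitutive reporter matures only where oxygen penetrates, so its
intensity as a function of Euclidean distance to the air-facing colony
surface is the pipeline's oxygen-exposure proxy.  Three sampling geometries
are provided: a thin vertical cylinder on the colony axis, a horizontal
plane at the colony base, and full isotropic distance shells.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.stats import linregress
from skimage import filters

from .types import AxialProfile, ColonyMask, ShellProfile, SurfaceDistanceMap, VoxelImage

__all__ = [
    "surface_distance_map",
    "shell_profile",
    "axial_cylinder_profile",
    "basal_plane_profile",
    "fluorescent_fraction",
    "fit_decay_length",
    "estimate_background",
]


def surface_distance_map(mask: ColonyMask, include_base: bool = False) -> SurfaceDistanceMap:
    """Euclidean distance (µm) from every colony voxel to the air-facing surface.

    A mask voxel is *surface* when one of its 6-neighbours is air: a
    non-mask voxel inside the grid, or outside the grid laterally or above.
    Below the bottom slice lies the substrate, which does not count as air
    unless ``include_base`` is set.  The transform is anisotropy-aware and
    agrees exactly with the brute-force minimum over surface voxels of the
    centre-to-centre Euclidean distance.
    """
    data = mask.data
    if not data.any():
        raise ValueError("empty colony mask")
    dx, dy, dz = mask.voxel_size
    # pad with air everywhere except below z=0 (substrate)
    padded = np.pad(data, 1, mode="constant", constant_values=False)
    if not include_base:
        padded[0, :, :] = padded[1, :, :]  # mirror: substrate neighbour never exposes a voxel
    air = ~padded
    surface = np.zeros_like(data)
    core = data
    surface |= core & air[:-2, 1:-1, 1:-1]   # below (only if include_base, else mirrored away)
    surface |= core & air[2:, 1:-1, 1:-1]    # above
    surface |= core & air[1:-1, :-2, 1:-1]
    surface |= core & air[1:-1, 2:, 1:-1]
    surface |= core & air[1:-1, 1:-1, :-2]
    surface |= core & air[1:-1, 1:-1, 2:]
    if not surface.any():
        raise ValueError("mask has no air-facing surface voxel")
    dist = ndimage.distance_transform_edt(~surface, sampling=(dz, dy, dx))
    return SurfaceDistanceMap(np.where(data, dist, np.nan), mask.voxel_size, includes_base=include_base)


def shell_profile(
    intensity: np.ndarray,
    distmap: SurfaceDistanceMap,
    bin_width_um: float = 2.0,
    normalize: bool = True,
    surface_reference_um: float = 2.0,
) -> ShellProfile:
    """Mean intensity over all colony voxels at a similar distance to the surface.

    Voxels are grouped into distance bins of ``bin_width_um``; empty bins
    report NaN.  When ``normalize`` is on, intensities are divided by the
    mean over the outermost ``surface_reference_um`` of the colony.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d = distmap.data
    inside = np.isfinite(d)
    dv = d[inside]
    iv = np.asarray(intensity, dtype=np.float64)[inside]
    n_bins = int(np.floor(dv.max() / bin_width_um)) + 1 if dv.size else 0
    idx = np.minimum(np.floor(dv / bin_width_um).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=iv, minlength=n_bins)
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    normalized = None
    if normalize:
        ref_sel = dv <= surface_reference_um
        ref = iv[ref_sel].mean() if ref_sel.any() else np.nan
        normalized = means / ref
    return ShellProfile(centers, means, counts, bin_width_um, normalized)


def axial_cylinder_profile(
    image_channel: np.ndarray,
    mask: ColonyMask,
    cylinder_radius_um: float = 3.3,
    surface_reference_um: float = 2.0,
) -> AxialProfile:
    """Mean intensity per z inside a vertical cylinder on the colony axis.

    The cylinder (default radius 3.3 µm) is centred on the basal-footprint
    centroid; the profile is normalized to the mean over the topmost
    occupied ``surface_reference_um`` of the cylinder, i.e. the fluorescence
    at the colony surface.
    """
    from .geometry import _footprint_center

    cx, cy, base_z = _footprint_center(mask)
    dx, dy, dz = mask.voxel_size
    nz, ny, nx = mask.data.shape
    x = (np.arange(nx) + 0.5) * dx - cx
    y = (np.arange(ny) + 0.5) * dy - cy
    in_cyl = np.hypot(x[None, :], y[:, None]) <= cylinder_radius_um
    sel = mask.data & in_cyl[None, :, :]
    if not sel.any():
        raise ValueError("sampling cylinder contains no colony voxels")
    vol = np.asarray(image_channel, dtype=np.float64)
    counts = sel.reshape(nz, -1).sum(axis=1)
    sums = np.where(sel, vol, 0.0).reshape(nz, -1).sum(axis=1)
    means = np.divide(sums, counts, out=np.full(nz, np.nan), where=counts > 0)
    z_um = (np.arange(nz) - base_z + 0.5) * dz
    occ = np.nonzero(counts > 0)[0]
    top = occ[-1]
    n_ref = max(1, int(round(surface_reference_um / dz)))
    ref_slices = occ[occ > top - n_ref] if occ.size else occ
    ref = float(np.sum(sums[ref_slices]) / np.sum(counts[ref_slices]))
    return AxialProfile(z_um, means, means / ref, ref, cylinder_radius_um)


def basal_plane_profile(
    image_channel: np.ndarray,
    mask: ColonyMask,
    base_z: int | None = None,
    bin_width_um: float = 2.0,
) -> ShellProfile:
    """Intensity vs in-plane distance to the colony edge in the base slice.

    The horizontal analogue of the axial profile: within the basal
    footprint, pixels are binned by 2D Euclidean distance to the footprint
    edge, and bin means are normalized by the edge (surface) bin.
    """
    data = mask.data
    if base_z is None:
        occupied = np.nonzero(data.any(axis=(1, 2)))[0]
        if occupied.size == 0:
            raise ValueError("empty colony mask")
        base_z = int(occupied[0])
    footprint = data[base_z]
    if not footprint.any():
        raise ValueError("base slice is empty")
    dx, dy, _ = mask.voxel_size
    edge_dist = ndimage.distance_transform_edt(footprint, sampling=(dy, dx))
    vol = np.asarray(image_channel, dtype=np.float64)
    plane = vol[base_z] if vol.ndim == 3 else vol
    dmap2d = SurfaceDistanceMap(
        np.where(footprint, edge_dist - min(dx, dy) / 2.0, np.nan).clip(min=0)[None, :, :],
        mask.voxel_size,
    )
    return shell_profile(plane[None, :, :], dmap2d, bin_width_um=bin_width_um, normalize=True,
                         surface_reference_um=bin_width_um)


def fluorescent_fraction(
    intensity: np.ndarray, mask: ColonyMask, threshold: float | str = "otsu"
) -> float:
    """Fluorescent volume fraction: mask voxels above threshold / all mask voxels.

    ``threshold`` is a fixed intensity or ``"otsu"`` (computed within the mask).
    """
    data = mask.data
    if not data.any():
        raise ValueError("empty colony mask")
    vals = np.asarray(intensity, dtype=np.float64)[data]
    if threshold == "otsu":
        threshold = filters.threshold_otsu(vals)
    elif not np.isscalar(threshold) or threshold < 0:
        raise ValueError("threshold must be 'otsu' or a non-negative number")
    return float((vals > threshold).mean())


def fit_decay_length(profile: ShellProfile | AxialProfile, min_count: int = 50,
                     max_distance_um: float | None = None, min_relative: float = 0.05):
    """Exponential decay length λ̂ (µm) from a log-linear least-squares fit.

    For a :class:`ShellProfile`, fits log(mean intensity) against shell
    distance over populated bins (count ≥ ``min_count``, positive mean);
    for an :class:`AxialProfile`, against depth below the apex.  Bins whose
    mean has fallen below ``min_relative`` of the brightest bin are excluded
    — in log space additive background and read noise dominate there.
    Returns ``(lambda_hat_um, r_squared)``.
    """
    if isinstance(profile, AxialProfile):
        ok = np.isfinite(profile.mean_intensity)
        depth = profile.z_um[ok].max() - profile.z_um[ok]
        vals = profile.mean_intensity[ok]
        x, y = depth, vals
    else:
        ok = (profile.n_voxels >= min_count) & np.isfinite(profile.mean_intensity)
        x, y = profile.bin_center_um[ok], profile.mean_intensity[ok]
    pos = y > 0
    x, y = x[pos], y[pos]
    if y.size and min_relative > 0:
        keep = y >= min_relative * y.max()
        x, y = x[keep], y[keep]
    if max_distance_um is not None:
        sel = x <= max_distance_um
        x, y = x[sel], y[sel]
    if x.size < 4:
        raise ValueError("need at least 4 populated bins with positive means to fit a decay length")
    res = linregress(x, np.log(y))
    if res.slope >= 0:
        raise ValueError("profile does not decay; decay length undefined")
    return float(-1.0 / res.slope), float(res.rvalue**2)


def estimate_background(intensity: np.ndarray, mask: ColonyMask) -> float:
    """Median intensity outside the colony mask (camera background estimate)."""
    outside = ~mask.data
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(intensity, dtype=np.float64)[outside]))
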