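"""Dead-cell fractions, ratiometric growth readout, competition ring ratios.

All three measurements are restricted to the *oxic shell* — colony voxels
within a fixed distance (default 30 µm) of the air-facing surface — because
only there does oxygen-dependent chromophore maturation make the reporters
trustworthy.  Heights are z above the base plane, so binning uses a
different coordinate (height) than the oxic restriction (distance to
surface); both are required.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters

from .types import ColonyMask, CompetitionResult, SurfaceDistanceMap, ViabilityProfile

__all__ = [
    "dead_fraction_profile",
    "reporter_ratio_foldchange",
    "competition_ring_ratio",
    "normalize_signal",
]


def _threshold_within_mask(intensity: np.ndarray, mask3d: np.ndarray, rule, fixed: float | None) -> float:
    if rule == "fixed":
        if fixed is None:
            raise ValueError("threshold_rule 'fixed' requires an explicit threshold value")
        return float(fixed)
    vals = np.asarray(intensity, dtype=np.float64)[mask3d]
    return float(filters.threshold_otsu(vals))


def _height_um(shape_z: int, dz: float, base_z: int) -> np.ndarray:
    return (np.arange(shape_z) - base_z + 0.5) * dz


def dead_fraction_profile(
    stable_ch: np.ndarray,
    dead_ch: np.ndarray,
    mask: ColonyMask,
    distmap: SurfaceDistanceMap,
    shell_depth_um: float = 30.0,
    height_bin_um: float = 10.0,
    threshold_rule: str = "otsu",
    stable_threshold: float | None = None,
    dead_threshold: float | None = None,
    base_z: int = 0,
) -> ViabilityProfile:
    """Dead-cell fraction per height bin within the oxic shell.

    Each channel is thresholded within the colony mask (Otsu by default);
    the fraction in a bin is the thresholded volume present in both the
    stable-reporter and dead-stain channels divided by the thresholded
    stable-reporter volume.  Only voxels within ``shell_depth_um`` of the
    air-facing surface contribute.  Bins with no stable-positive voxels are
    reported as NaN.
    """
    if shell_depth_um <= 0 or height_bin_um <= 0:
        raise ValueError("shell depth and height bin must be > 0")
    m = mask.data
    thr_s = _threshold_within_mask(stable_ch, m, threshold_rule, stable_threshold)
    thr_d = _threshold_within_mask(dead_ch, m, threshold_rule, dead_threshold)
    stable_pos = m & (np.asarray(stable_ch) > thr_s)
    dead_pos = m & (np.asarray(dead_ch) > thr_d)
    oxic = m & (distmap.data <= shell_depth_um)
    stable_pos &= oxic
    if not stable_pos.any():
        raise ValueError("no stable-reporter-positive voxels inside the oxic shell")
    both = stable_pos & dead_pos

    dz = mask.voxel_size[2]
    z_um = _height_um(m.shape[0], dz, base_z)
    n_bins = int(np.floor(z_um[m.any(axis=(1, 2))].max() / height_bin_um)) + 1
    bin_of_z = np.clip(np.floor(z_um / height_bin_um).astype(int), 0, n_bins - 1)
    n_stable = np.zeros(n_bins)
    n_both = np.zeros(n_bins)
    for k in range(m.shape[0]):
        b = bin_of_z[k]
        if b < 0:
            continue
        n_stable[b] += stable_pos[k].sum()
        n_both[b] += both[k].sum()
    frac = np.divide(n_both, n_stable, out=np.full(n_bins, np.nan), where=n_stable > 0)
    centers = (np.arange(n_bins) + 0.5) * height_bin_um
    return ViabilityProfile(centers, frac, n_stable.astype(int), shell_depth_um, height_bin_um)


def reporter_ratio_foldchange(
    unstable_ch: np.ndarray,
    stable_ch: np.ndarray,
    mask: ColonyMask,
    distmap: SurfaceDistanceMap,
    h_hi_um: float = 100.0,
    h_lo_um: float = 0.0,
    shell_depth_um: float = 30.0,
    height_bin_um: float = 10.0,
    background_unstable: float = 0.0,
    background_stable: float = 0.0,
    base_z: int = 0,
):
    """Unstable/stable reporter ratio per height bin and its fold-change.

    The ratio in a bin is the quotient of background-subtracted channel
    *sums* over the bin's oxic-shell voxels (a sum quotient, not a mean of
    per-voxel quotients, which is unstable at dim voxels).  Height bins of
    width ``height_bin_um`` are centred on multiples of the bin width so the
    query heights fall at bin centres; the fold-change is
    ratio(bin at ``h_hi_um``) / ratio(bin at ``h_lo_um``).

    Returns ``(fold_change, table)`` where ``table`` has columns
    height_um, ratio, n_voxels.
    """
    import pandas as pd

    m = mask.data
    oxic = m & (distmap.data <= shell_depth_um)
    dz = mask.voxel_size[2]
    z_um = _height_um(m.shape[0], dz, base_z)
    top = z_um[m.any(axis=(1, 2))].max()
    if h_hi_um > top + height_bin_um / 2:
        raise ValueError(f"query height {h_hi_um} µm exceeds the colony height ({top:.1f} µm)")
    u = np.asarray(unstable_ch, dtype=np.float64) - background_unstable
    s = np.asarray(stable_ch, dtype=np.float64) - background_stable

    # bin centres at k*height_bin_um, edges at (k ± 0.5)*height_bin_um
    bin_idx = np.round(z_um / height_bin_um).astype(int)
    n_bins = bin_idx[m.any(axis=(1, 2))].max() + 1
    sums_u = np.zeros(n_bins)
    sums_s = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(m.shape[0]):
        b = bin_idx[k]
        if b < 0 or b >= n_bins:
            continue
        sel = oxic[k]
        sums_u[b] += u[k][sel].sum()
        sums_s[b] += s[k][sel].sum()
        counts[b] += sel.sum()
    ratio = np.divide(sums_u, sums_s, out=np.full(n_bins, np.nan), where=sums_s > 0)
    centers = np.arange(n_bins) * height_bin_um
    table = pd.DataFrame({"height_um": centers, "ratio": ratio, "n_voxels": counts})

    def _ratio_at(h):
        b = int(round(h / height_bin_um))
        if b < 0 or b >= n_bins or not np.isfinite(ratio[b]) or sums_s[b] <= 0:
            raise ValueError(f"no usable stable-reporter signal in the bin at height {h} µm")
        return ratio[b]

    fold = float(_ratio_at(h_hi_um) / _ratio_at(h_lo_um))
    return fold, table


def competition_ring_ratio(
    ch1: np.ndarray,
    ch2: np.ndarray,
    inoculum_mask: np.ndarray,
    pixel_um: float,
    ring_distance_um: float = 350.0,
    ring_width_um: float = 35.0,
    threshold_rule: str = "otsu",
    thresholds: tuple[float, float] | None = None,
) -> CompetitionResult:
    """Strain-1 area fraction in a ring around the inoculation spot.

    The ring collects pixels whose Euclidean distance to the inoculum edge
    lies in ``[ring_distance, ring_distance + ring_width]``; each channel is
    thresholded within the ring and the fraction is area₁/(area₁+area₂).
    """
    inoculum = np.asarray(inoculum_mask, dtype=bool)
    if not inoculum.any():
        raise ValueError("empty inoculum footprint")
    dist = ndimage.distance_transform_edt(~inoculum, sampling=(pixel_um, pixel_um))
    ring = (dist >= ring_distance_um) & (dist <= ring_distance_um + ring_width_um)
    if not ring.any():
        raise ValueError("competition ring is empty (image too small for the requested geometry)")
    a1 = np.asarray(ch1, dtype=np.float64)[ring]
    a2 = np.asarray(ch2, dtype=np.float64)[ring]
    if thresholds is not None:
        t1, t2 = thresholds
    elif threshold_rule == "otsu":
        t1, t2 = filters.threshold_otsu(a1), filters.threshold_otsu(a2)
    else:
        raise ValueError("provide fixed thresholds or use threshold_rule='otsu'")
    n1 = int((a1 > t1).sum())
    n2 = int((a2 > t2).sum())
    if n1 + n2 == 0:
        raise ValueError("no pixels above threshold in either channel within the ring")
    px_area = pixel_um**2
    return CompetitionResult(
        ring_inner_um=ring_distance_um,
        ring_outer_um=ring_distance_um + ring_width_um,
        fraction_strain1=n1 / (n1 + n2),
        area1_um2=n1 * px_area,
        area2_um2=n2 * px_area,
    )


def normalize_signal(signal: float, denom: float, mode: str = "biovolume") -> dict:
    """Normalize a bulk signal by biovolume, OD, or colony-number × mean volume.

    Returns ``{"value": signal/denom, "mode": mode}`` so downstream tables
    record which normalization was applied.
    """
    if denom <= 0:
        raise ValueError("normalization denominator must be > 0")
    if mode not in ("biovolume", "od", "count_x_volume"):
        raise ValueError("mode must be 'biovolume', 'od' or 'count_x_volume'")
    return {"value": signal / denom, "mode": mode}
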