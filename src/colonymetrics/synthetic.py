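"""Synthetic colony-biofilm image generator with exact ground truth.

Renders calibrated multi-channel 3D stacks that emulate the statistical
structure the downstream analyses assume:

* a dome-shaped colony ``h(r) = H (1 - (r/R)^p)`` sitting on a flat substrate
  (``p = 1`` a cone, ``p = 2`` a convex "bulged" dome);
* a constitutive stable-reporter channel whose noiseless intensity decays
  exponentially with the true Euclidean distance to the air-facing surface —
  a proxy for oxygen-dependent chromophore maturation;
* a dead-cell stain channel colocalized with a height-dependent Bernoulli
  subset of colony voxels (clamped linear ramp in height);
* an unstable-reporter channel whose ratio to the stable reporter varies
  linearly with height (a growth-rate readout surrogate);
* sparse bright beads in the substrate plane outside the colony footprint,
  used by the focal-plane locator;
* Poisson shot noise on signal plus background, then additive Gaussian read
  noise.

Every stochastic element is driven by a single seed, so equal specs produce
bitwise-equal stacks, and the noiseless fields plus per-voxel labels are
returned as :class:`GroundTruth` for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .types import ColonyMask, SurfaceDistanceMap, VoxelImage

__all__ = [
    "SyntheticColonySpec",
    "GroundTruth",
    "shape_height",
    "render_colony",
    "render_overview",
    "render_competition",
]


@dataclass
class SyntheticColonySpec:
    """Parameters of one synthetic colony.

    Lengths in µm, intensities in arbitrary detector counts.  The defaults
    describe a desk-scale colony: 120 µm tall and 120 µm in basal radius
    (real colonies are far wider than tall; the aspect is compressed here to
    keep grids small while preserving every analyzed structure), with a
    20 µm fluorescence decay length, a death ramp rising from 50 µm to
    150 µm height with ceiling 0.3, and a reporter ratio that doubles
    between heights 0 and 100 µm.
    """

    H: float = 120.0               # apex height
    R: float = 120.0               # basal radius
    bulge_p: float = 2.0           # shape exponent; 1 = cone, 2 = bulged dome
    lambda_decay: float = 20.0     # fluorescence decay length (oxygen proxy)
    surface_intensity: float = 200.0
    dead_params: tuple[float, float, float] = (50.0, 150.0, 0.3)   # (d0, d1, pmax)
    ratio_params: tuple[float, float] = (0.5, 0.01)                # (g0, g1 per µm)
    mix_fraction: float = 0.5      # strain-1 fraction (competition mode)
    poisson_on: bool = True
    read_sigma: float = 3.0
    background: float = 10.0
    bead_intensity: float = 1000.0
    n_beads: int = 12
    margin_um: float = 6.0
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.H <= 0 or self.R <= 0:
            raise ValueError("H and R must be strictly positive")
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be strictly positive")
        if self.bulge_p < 1:
            raise ValueError("bulge_p must be >= 1")
        d0, d1, pmax = self.dead_params
        if not (0.0 <= pmax <= 1.0):
            raise ValueError("pmax must lie in [0, 1]")
        if d1 <= d0:
            raise ValueError("dead_params requires d1 > d0")
        if not (0.0 <= self.mix_fraction <= 1.0):
            raise ValueError("mix_fraction must lie in [0, 1]")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Noiseless fields and per-voxel labels for one rendered colony."""

    mask: ColonyMask
    true_distance: SurfaceDistanceMap
    noiseless: dict[str, np.ndarray]
    dead_label: np.ndarray
    bead_centers_um: np.ndarray  # (n, 2) xy positions
    strain_label: np.ndarray | None = None


def shape_height(r, spec: SyntheticColonySpec):
    """Colony height h(r) = H·(1 − (r/R)^p), clamped to 0 beyond the rim.

    Continuous and non-increasing in r; h(0) = H, h(R) = 0.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("radial distance must be >= 0")
    frac = np.clip(r / spec.R, 0.0, 1.0)
    return spec.H * (1.0 - frac ** spec.bulge_p)


def _true_surface_distance(r2d: np.ndarray, z_centers: np.ndarray, spec: SyntheticColonySpec) -> np.ndarray:
    """Distance from each voxel centre to the dome surface z = h(r), r ∈ [0, R].

    By axisymmetry the 3D distance to the surface of revolution equals the 2D
    distance from (r, z) to the meridian curve, so the curve is rasterized on
    a fine isotropic (r, z) grid and an exact Euclidean distance transform is
    interpolated at the voxel coordinates.
    """
    step = min(min(spec.voxel_size), 1.0) / 4.0
    r_max = float(r2d.max()) + 2 * step
    z_max = float(z_centers.max()) + 2 * step
    nr = int(math.ceil(r_max / step)) + 2
    nz = int(math.ceil(z_max / step)) + 2
    curve = np.zeros((nz, nr), dtype=bool)
    # parametrize densely enough that consecutive samples land on adjacent pixels
    arc_n = int(4 * (nr + nz))
    t = np.linspace(0.0, spec.R, arc_n)
    zc = shape_height(t, spec)
    ir = np.clip(np.round(t / step).astype(int), 0, nr - 1)
    iz = np.clip(np.round(zc / step).astype(int), 0, nz - 1)
    curve[iz, ir] = True
    dist = ndimage.distance_transform_edt(~curve, sampling=(step, step))
    # bilinear interpolation at (z, r) voxel coordinates
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (np.arange(nz) * step, np.arange(nr) * step), dist, bounds_error=False, fill_value=None
    )
    zz = np.broadcast_to(z_centers[:, None, None], (len(z_centers),) + r2d.shape)
    rr = np.broadcast_to(r2d[None, :, :], zz.shape)
    pts = np.stack([zz.ravel(), rr.ravel()], axis=1)
    return interp(pts).reshape(zz.shape)


def _grid(spec: SyntheticColonySpec):
    dx, dy, dz = spec.voxel_size
    nx = int(math.ceil((2 * spec.R + 2 * spec.margin_um) / dx))
    ny = int(math.ceil((2 * spec.R + 2 * spec.margin_um) / dy))
    nz = int(math.ceil((spec.H + spec.margin_um) / dz))
    if nx < 4 or ny < 4 or nz < 2:
        raise ValueError("grid too small to contain the colony plus margin")
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    x = (np.arange(nx) + 0.5) * dx - cx
    y = (np.arange(ny) + 0.5) * dy - cy
    r2d = np.hypot(x[None, :], y[:, None])
    z_centers = (np.arange(nz) + 0.5) * dz
    return (nx, ny, nz), (cx, cy), r2d, z_centers


def _apply_noise(clean: np.ndarray, spec: SyntheticColonySpec, rng: np.random.Generator) -> np.ndarray:
    img = clean + spec.background
    if spec.poisson_on:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    if spec.read_sigma > 0:
        img = img + rng.normal(0.0, spec.read_sigma, size=img.shape)
    return img


def render_colony(spec: SyntheticColonySpec) -> tuple[VoxelImage, GroundTruth]:
    """Render one colony stack with channels stable_reporter, dead_stain,
    unstable_reporter, beads, plus its :class:`GroundTruth`."""
    rng = np.random.default_rng(spec.seed)
    (nx, ny, nz), (cx, cy), r2d, z_centers = _grid(spec)
    dx, dy, dz = spec.voxel_size

    h_r = shape_height(r2d, spec)                      # (ny, nx)
    mask = z_centers[:, None, None] < h_r[None, :, :]  # (nz, ny, nx)
    if not mask.any():
        raise ValueError("grid too small: colony does not occupy any voxel")

    dist = _true_surface_distance(r2d, z_centers, spec)
    dist = np.where(mask, dist, np.nan)

    stable = np.where(mask, spec.surface_intensity * np.exp(-np.where(mask, dist, 0.0) / spec.lambda_decay), 0.0)

    d0, d1, pmax = spec.dead_params
    p_dead = pmax * np.clip((z_centers - d0) / (d1 - d0), 0.0, 1.0)
    dead_label = (rng.random(mask.shape) < p_dead[:, None, None]) & mask
    dead_ch = np.where(dead_label, stable, 0.0)

    g0, g1 = spec.ratio_params
    ratio_z = g0 * (1.0 + g1 * z_centers)
    unstable = ratio_z[:, None, None] * stable

    beads = np.zeros(mask.shape)
    bead_centers = []
    attempts = 0
    while len(bead_centers) < spec.n_beads and attempts < 10_000:
        attempts += 1
        i = int(rng.integers(1, nx - 2))
        j = int(rng.integers(1, ny - 2))
        bx = (i + 0.5) * dx - cx
        by = (j + 0.5) * dy - cy
        if math.hypot(bx, by) <= spec.R + 2.0:   # keep beads off the colony footprint
            continue
        if beads[0, j : j + 2, i : i + 2].any():
            continue
        beads[0, j : j + 2, i : i + 2] = spec.bead_intensity
        bead_centers.append((bx + cx + dx / 2.0, by + cy + dy / 2.0))
    if len(bead_centers) < min(spec.n_beads, 10):
        raise ValueError("could not place beads outside the colony footprint; enlarge margin")

    noiseless = {
        "stable_reporter": stable,
        "dead_stain": dead_ch,
        "unstable_reporter": unstable,
        "beads": beads,
    }
    channels = {name: _apply_noise(arr, spec, rng) for name, arr in noiseless.items()}

    image = VoxelImage(channels, spec.voxel_size)
    truth = GroundTruth(
        mask=ColonyMask(mask, spec.voxel_size),
        true_distance=SurfaceDistanceMap(dist, spec.voxel_size, includes_base=False),
        noiseless=noiseless,
        dead_label=dead_label,
        bead_centers_um=np.asarray(bead_centers, dtype=np.float64),
    )
    return image, truth


def render_overview(
    n_colonies: int,
    spec: SyntheticColonySpec,
    field_um: float = 2000.0,
    pixel_um: float = 2.0,
    gap_um: float = 20.0,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """2D overview scan of a filter membrane carrying ``n_colonies`` disks.

    Returns the noisy image and the true colony centres (µm, xy), pairwise
    separated by more than ``2R + gap`` by construction.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = np.random.default_rng(spec.seed)
    n_px = int(round(field_um / pixel_um))
    x = (np.arange(n_px) + 0.5) * pixel_um
    xx, yy = np.meshgrid(x, x)
    img = np.zeros((n_px, n_px))
    centers = []
    min_sep = 2 * spec.R + gap_um
    for _ in range(n_colonies):
        for attempt in range(max_attempts):
            c = rng.uniform(spec.R + gap_um, field_um - spec.R - gap_um, size=2)
            if all(math.hypot(c[0] - p[0], c[1] - p[1]) > min_sep for p in centers):
                centers.append(tuple(c))
                img[np.hypot(xx - c[0], yy - c[1]) <= spec.R] = spec.surface_intensity
                break
        else:
            raise RuntimeError(f"could not place colony {len(centers) + 1} without overlap in {max_attempts} attempts")
    img = img + spec.background
    if spec.poisson_on:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    if spec.read_sigma > 0:
        img = img + rng.normal(0.0, spec.read_sigma, size=img.shape)
    return img, np.asarray(centers, dtype=np.float64).reshape(-1, 2)


def render_competition(
    spec: SyntheticColonySpec,
    inoculum_radius_um: float = 150.0,
    spread_um: float = 500.0,
    pixel_um: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """2D two-strain competition image (top view of an expanded colony).

    The colony footprint is a disk of radius ``inoculum_radius + spread``;
    each footprint pixel belongs to strain 1 with probability
    ``spec.mix_fraction`` (per-pixel Bernoulli).  Returns
    ``(channel1, channel2, inoculum_mask, strain1_label)``.
    """
    rng = np.random.default_rng(spec.seed)
    r_col = inoculum_radius_um + spread_um
    field = 2 * (r_col + 4 * pixel_um)
    n_px = int(round(field / pixel_um))
    x = (np.arange(n_px) + 0.5) * pixel_um - field / 2.0
    rr = np.hypot(x[None, :], x[:, None])
    footprint = rr <= r_col
    inoculum = rr <= inoculum_radius_um
    strain1 = (rng.random(footprint.shape) < spec.mix_fraction) & footprint
    ch1 = np.where(strain1, spec.surface_intensity, 0.0)
    ch2 = np.where(footprint & ~strain1, spec.surface_intensity, 0.0)
    ch1 = _apply_noise(ch1, spec, rng)
    ch2 = _apply_noise(ch2, spec, rng)
    return ch1, ch2, inoculum, strain1
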