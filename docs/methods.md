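# Methods

This note documents the measurement model, the synthetic data the package
validates itself against, and the numerical choices made where the
procedure definitions leave freedom.

## Coordinate conventions

Arrays are `(z, y, x)`; the colony base (filter-membrane side) is at
z-index 0, voxel centres at `(k + 0.5)·dz` µm above the base plane. Stacks
recorded apex-down (inverted microscopes image colonies facing the
objective) are flipped at ingestion via the `z_orientation: apex_low`
config flag, so all downstream code sees one orientation. All physical
quantities are µm internally; voxel indices never cross module boundaries.
The base plane is located from the beads channel (z-slice maximizing total
bead intensity) when present, otherwise from the lowest segmented slice.

## Segmentation and biovolume

The colony outline in each z-slice is obtained by thresholding the
gradient magnitude (Sobel) of the Gaussian-smoothed slice (σ = 1 px
default). The threshold is automatic by default: a single Otsu threshold
over the gradient magnitudes of the *whole stack*, not per slice — slices
above the colony contain only camera noise, and a per-slice threshold
would hallucinate outlines there. A fixed threshold can be configured for
strict reproducibility across runs.

The supra-threshold gradient band straddles the true intensity edge
(symmetric for a smoothed step), so the filled region is biased outward by
half the band width — enough to inflate a 50 µm hemisphere's volume by
~5%. The segmenter therefore erodes the filled largest component by the
estimated band half-width, computed from the equivalent-disk radii of the
filled region and its band-free interior. With this centring, the
hemisphere biovolume error is 0.8% at 1 µm voxels and 0.5% at 0.5 µm.

Biovolume is the sum over slices of the *convex* area of the per-slice
outline times the z-step. The convex hull makes the measure insensitive to
interior darkness (deep colony regions are non-fluorescent because oxygen
never reaches them), which is the point of using hull area as a per-plane
biomass proxy.

## Distance to the air-facing surface

A colony voxel is *surface* when a 6-neighbour is air: a non-colony voxel,
or outside the grid laterally/above. The substrate below z = 0 is not air
— oxygen arrives from the atmosphere, not through the filter — so voxels
exposed only downward are interior. (`include_base_as_surface` flips
this, default off.) Distances are computed with an exact anisotropy-aware
Euclidean distance transform (`scipy.ndimage.distance_transform_edt` with
per-axis sampling); unit tests verify exact agreement with a brute-force
minimum over surface voxels on random 32³ masks.

## Profiles and decay-length fit

* **Shell profile**: colony voxels grouped in distance bins (default
  2 µm); bin mean intensity, empty bins NaN. Normalization uses the mean
  over the outermost 2 µm shell rather than a single voxel, for noise
  robustness.
* **Axial profile**: mean intensity per z within a vertical cylinder of
  radius 3.3 µm centred on the basal-footprint centroid, normalized to the
  topmost occupied 2 µm of the cylinder. Near the apex the axial depth
  equals the surface distance (exactly, while depth is below the apex
  radius of curvature R²/2H).
* **Basal profile**: within the base-slice footprint, intensity vs 2D
  distance to the footprint edge. The in-plane distance only approximates
  the true surface distance near the rim (the ratio is sin θ of the rim
  wall angle), so the recovered decay length is biased high by
  1/sin θ — ~12% for the default dome, within the 15% agreement the three
  geometries are tested to.
* **Decay fit**: least-squares line to log(mean) vs distance over bins
  with ≥ 50 voxels (shell) and positive means; λ̂ = −1/slope, R² reported.
  Bins below 5% of the brightest bin are excluded: after background
  subtraction their log-means are dominated by residual background and
  read noise. Background is estimated as the median intensity outside the
  colony mask and subtracted before profile fits and ratio measurements.

## Viability and growth ratio

Dead-cell fraction per height bin = |stable⁺ ∧ dead⁺| / |stable⁺|, with
per-channel thresholds computed by Otsu *within the colony mask* (so
background outside the colony cannot skew them; fixed thresholds are a
config option), restricted to the oxic shell (distance ≤ 30 µm). Height
bins default to 10 µm; bins without stable-positive voxels are NaN.

The growth readout is the ratio of background-subtracted channel *sums*
per height bin — a quotient of sums, not a mean of per-voxel quotients,
which is unstable where the denominator is dim. Height bins are centred on
multiples of the bin width so the query heights (100 and 0 µm) fall at bin
centres; the fold-change is the ratio of those two bins. With a linear
ratio field doubling over 100 µm, the bin at height 0 averages voxels at
0–5 µm, which biases the measured fold-change ≈3% below the true
voxel-level doubling; this discretization floor is visible in the
noiseless recovery (1.94 vs 2.0).

Competition: the ring is the set of pixels whose Euclidean distance to the
inoculum-footprint edge lies in [350, 385] µm; each channel is Otsu-
thresholded within the ring and the reported fraction is
area₁/(area₁ + area₂), so a channel swap gives the exact complement.

## Morphometry

The height–radius profile takes, per one-voxel-wide radial bin around the
basal-footprint centroid, the azimuthal mean of the top face of the
topmost occupied voxel (the mean is used rather than the max, which is
noise-sensitive). No monotone cleanup is applied, preserving mid-height
bulges. The bulge metric is dh/dr where the moving-average-smoothed
profile (window 5 bins, configurable) crosses the query height (default
100 µm), using `np.gradient` interpolated at the crossing radius. On
analytic solids this recovers the cone slope −H/R exactly and the
hemisphere slope −√3 at half height to 0.4%.

## Synthetic colonies

The generator renders what the analyses assume, with exact ground truth:

* **Shape** `h(r) = H(1 − (r/R)^p)`, p = 1 a cone, p = 2 a convex dome.
  Defaults H = 120 µm, R = 120 µm: tall enough that the 100 µm query
  height lies in the upper quarter of the dome, where the p = 2 dome is
  genuinely *less* steep than the cone (for this family the contrast at
  height h flips sign at h/H = 3/4), and with a rim steep enough
  (|dh/dr| = 2 at the edge) that the basal in-plane distance remains a
  usable surface-distance proxy. Real colonies are much wider than tall;
  the compressed aspect keeps desk-scale grids small while preserving
  every measured structure, and nothing in the pipeline depends on it.
* **Oxygen proxy** `I = I₀·exp(−d/λ)` with d the true distance to the dome
  surface, computed to ±0.25 µm by an exact distance transform on a finely
  rasterized meridian curve (by axisymmetry the 3D distance to the surface
  of revolution equals the 2D distance to the curve). The exponential form
  is a generator choice — it makes λ exactly recoverable — not a claim
  about oxygen physics; defaults λ = 20 µm, I₀ = 200 counts.
* **Death field**: per-voxel Bernoulli with p(z) = p_max·clamp((z−d₀)/(d₁−d₀), 0, 1),
  defaults d₀ = 50 µm, d₁ = 150 µm, p_max = 0.3 — death increasing toward
  the colony top. The dead-stain channel copies the stable-reporter
  intensity at dead voxels, so the colocalization measurement is
  non-trivial yet exactly invertible.
* **Growth ratio**: unstable = g₀(1 + g₁z)·stable with g₀ = 0.5,
  g₁ = 0.01 µm⁻¹, i.e. the ratio doubles between heights 0 and 100 µm.
* **Beads**: ≥ 10 bright 2×2×1-voxel spots in the base plane outside the
  colony footprint.
* **Noise**: Poisson on signal + background (10 counts), then additive
  Gaussian read noise (σ = 3) — shot + read noise of sCMOS/EMCCD
  detection, applied in that order. One `numpy` Generator seeded from the
  spec drives everything: equal specs give bitwise-equal stacks.

What the generator does **not** emulate: single cells and their packing
texture, optical blur (PSF), depth-dependent attenuation other than the
oxygen proxy itself, refractive-index artifacts, motility, or any real
oxygen reaction–diffusion physics. Passing recovery tests therefore
demonstrates that the measurement procedures are correct and unbiased on
images with realistic noise and exactly known structure — not that the
biological conclusions drawn from real colonies are reproduced here.

## Problem sizes and degenerate inputs

Recovery tests use colonies of H = R = 120 µm at 1×1×2 µm voxels
(~5×10⁶ voxels, ≈1.4×10⁶ in the mask) and three replicate seeds; analytic
slope checks use a 200×400 µm cone and a 200 µm hemisphere at 1 µm voxels;
the distance-transform oracle uses 32³ random blob masks. These sizes put
≳10⁴ voxels in every asserted height bin, so binomial noise in the
dead-fraction check is ≲0.003 against the 0.02 assertion band.

Degenerate inputs are errors, not silent defaults: stacks without voxel
calibration, flat beads channels, empty masks, query heights above the
colony, flat (non-decaying) profiles, and zero normalization denominators
all raise with a message naming the problem; an empty segmented slice is a
valid result (area 0). Empty profile bins carry NaN and zero count.
Partial-volume voxels at the segmented boundary depress the outermost
shell bin's mean on coarse grids; the decay fit is insensitive to this
(single bin among many), but the normalized surface value can undershoot 1
at 2 µm voxels.
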