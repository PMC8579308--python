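"""Distance maps and fluorescence profiles: oracle equivalence and recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.spatial.distance import cdist

from colonymetrics import profiles
from colonymetrics.types import ColonyMask, ShellProfile, SurfaceDistanceMap, VoxelImage


def brute_force_surface_distance(mask: np.ndarray, voxel_size, include_base=False) -> np.ndarray:
    """Independent oracle: min over surface voxels of centre-to-centre distance."""
    dx, dy, dz = voxel_size
    padded = np.pad(mask, 1, constant_values=False)
    if not include_base:
        padded[0, :, :] = padded[1, :, :]
    air = ~padded
    surf = np.zeros_like(mask)
    surf |= mask & air[:-2, 1:-1, 1:-1]
    surf |= mask & air[2:, 1:-1, 1:-1]
    surf |= mask & air[1:-1, :-2, 1:-1]
    surf |= mask & air[1:-1, 2:, 1:-1]
    surf |= mask & air[1:-1, 1:-1, :-2]
    surf |= mask & air[1:-1, 1:-1, 2:]
    scale = np.array([dz, dy, dx])
    pts_m = np.argwhere(mask) * scale
    pts_s = np.argwhere(surf) * scale
    out = np.full(mask.shape, np.nan)
    out[mask] = cdist(pts_m, pts_s).min(axis=1)
    return out


def random_blob_mask(seed: int, n: int = 32) -> np.ndarray:
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=(n, n, n)), 4)
    return field > np.quantile(field, 0.7)


class TestSurfaceDistanceMap:
    def test_single_voxel_is_surface(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        dm = profiles.surface_distance_map(ColonyMask(m, (1, 1, 1)))
        assert dm.data[1, 1, 1] == 0.0

    def test_slab_depth_below_top_face(self):
        # wide slab 20 µm thick on the substrate: away from lateral edges the
        # distance is the depth below the top face (base is not surface)
        m = np.zeros((25, 60, 60), bool)
        m[:20, :, :] = True
        dm = profiles.surface_distance_map(ColonyMask(m, (1, 1, 1)))
        core = dm.data[:20, 25:35, 25:35]
        depth = 19 - np.arange(20)  # voxel-centre distance to the top surface voxel
        assert np.allclose(core, depth[:, None, None])

    def test_matches_brute_force_oracle(self):
        for seed, vs in [(0, (1.0, 1.0, 1.0)), (1, (0.7, 0.7, 1.3)), (2, (0.5, 0.5, 2.0))]:
            m = random_blob_mask(seed)
            dm = profiles.surface_distance_map(ColonyMask(m, vs))
            bf = brute_force_surface_distance(m, vs)
            assert np.allclose(dm.data[m], bf[m], atol=1e-9)

    def test_include_base_shrinks_distances(self):
        m = np.zeros((25, 40, 40), bool)
        m[:20, 5:35, 5:35] = True
        d_air = profiles.surface_distance_map(ColonyMask(m, (1, 1, 1)), include_base=False)
        d_all = profiles.surface_distance_map(ColonyMask(m, (1, 1, 1)), include_base=True)
        assert np.all(d_all.data[m] <= d_air.data[m] + 1e-12)
        assert d_all.data[0, 20, 20] == 0.0  # base voxel is surface when the base counts

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            profiles.surface_distance_map(ColonyMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))


class TestShellProfile:
    def test_uniform_colony_flat_profile(self, noiseless_colony):
        _, _, truth = noiseless_colony
        uniform = np.where(truth.mask.data, 100.0, 0.0)
        prof = profiles.shell_profile(uniform, truth.true_distance)
        ok = prof.n_voxels > 0
        assert np.allclose(prof.mean_intensity[ok], 100.0)
        assert np.allclose(prof.normalized[ok], 1.0)

    def test_exponential_field_bin_means(self, noiseless_colony):
        spec, _, truth = noiseless_colony
        prof = profiles.shell_profile(
            truth.noiseless["stable_reporter"], truth.true_distance, bin_width_um=2.0, normalize=False
        )
        sel = prof.n_voxels > 100
        expected = spec.surface_intensity * np.exp(-prof.bin_center_um[sel] / spec.lambda_decay)
        assert np.allclose(prof.mean_intensity[sel], expected, rtol=0.03)

    def test_monotone_field_gives_monotone_profile(self, noiseless_colony):
        _, _, truth = noiseless_colony
        prof = profiles.shell_profile(
            truth.noiseless["stable_reporter"], truth.true_distance, normalize=False
        )
        vals = prof.mean_intensity[prof.n_voxels > 0]
        assert np.all(np.diff(vals) < 0)

    def test_empty_bins_have_nan_mean(self):
        d = np.full((1, 4, 4), np.nan)
        d[0, 1:3, 1:3] = 0.5
        dm = SurfaceDistanceMap(d, (1, 1, 1))
        prof = profiles.shell_profile(np.ones((1, 4, 4)), dm, bin_width_um=0.2)
        assert prof.n_voxels[0] == 0 and np.isnan(prof.mean_intensity[0])
        assert prof.n_voxels[2] == 4


class TestAxialProfile:
    def test_uniform_colony_is_unity(self, noiseless_colony):
        _, _, truth = noiseless_colony
        uniform = np.where(truth.mask.data, 80.0, 0.0)
        prof = profiles.axial_cylinder_profile(uniform, truth.mask)
        ok = np.isfinite(prof.normalized)
        assert np.allclose(prof.normalized[ok], 1.0)

    def test_default_cylinder_radius(self, noiseless_colony):
        _, _, truth = noiseless_colony
        prof = profiles.axial_cylinder_profile(truth.noiseless["stable_reporter"], truth.mask)
        assert prof.cylinder_radius_um == 3.3

    def test_exponential_decay_near_apex(self, noiseless_colony):
        spec, _, truth = noiseless_colony
        prof = profiles.axial_cylinder_profile(truth.noiseless["stable_reporter"], truth.mask)
        ok = np.isfinite(prof.mean_intensity)
        z = prof.z_um[ok]
        norm = prof.normalized[ok]
        z_top = z.max()
        for dz_below in (10, 20, 30, 40):
            val = np.interp(z_top - dz_below, z, norm)
            assert val == pytest.approx(math.exp(-dz_below / spec.lambda_decay), rel=0.05)

    def test_empty_cylinder_raises(self):
        # ring-shaped footprint: the centroid cylinder contains no colony voxel
        m = np.zeros((5, 40, 40), bool)
        x = (np.arange(40) + 0.5) - 20
        r = np.hypot(x[None, :], x[:, None])
        m[0] = (r > 10) & (r < 14)
        with pytest.raises(ValueError):
            profiles.axial_cylinder_profile(np.ones((5, 40, 40)), ColonyMask(m, (1, 1, 1)))


class TestBasalProfile:
    def test_uniform_slice_flat(self, noiseless_colony):
        _, _, truth = noiseless_colony
        uniform = np.where(truth.mask.data, 50.0, 0.0)
        prof = profiles.basal_plane_profile(uniform, truth.mask)
        ok = prof.n_voxels > 0
        assert np.allclose(prof.normalized[ok], 1.0)

    def test_single_pixel_footprint(self):
        m = np.zeros((2, 9, 9), bool)
        m[0, 4, 4] = True
        m[1, 4, 4] = True
        prof = profiles.basal_plane_profile(np.full((2, 9, 9), 7.0), ColonyMask(m, (1, 1, 1)))
        ok = prof.n_voxels > 0
        assert ok.sum() == 1 and prof.normalized[ok][0] == pytest.approx(1.0)

    def test_decay_length_recovered_in_plane(self, noiseless_colony):
        spec, _, truth = noiseless_colony
        prof = profiles.basal_plane_profile(truth.noiseless["stable_reporter"], truth.mask)
        lam, _ = profiles.fit_decay_length(prof, min_count=20)
        assert lam == pytest.approx(spec.lambda_decay, rel=0.15)


class TestFluorescentFraction:
    def test_threshold_above_max_gives_zero(self, noiseless_colony):
        _, _, truth = noiseless_colony
        f = profiles.fluorescent_fraction(truth.noiseless["stable_reporter"], truth.mask, 1e9)
        assert f == 0.0

    def test_threshold_zero_on_positive_field_gives_one(self, noiseless_colony):
        _, _, truth = noiseless_colony
        f = profiles.fluorescent_fraction(truth.noiseless["stable_reporter"], truth.mask, 0.0)
        assert f == 1.0

    def test_half_surface_threshold_matches_cap_geometry(self, noiseless_colony):
        spec, _, truth = noiseless_colony
        f = profiles.fluorescent_fraction(
            truth.noiseless["stable_reporter"], truth.mask, spec.surface_intensity / 2
        )
        d = truth.true_distance.data[truth.mask.data]
        expected = (d < spec.lambda_decay * math.log(2)).mean()
        assert f == pytest.approx(expected, abs=0.03)

    def test_non_increasing_in_threshold(self, noiseless_colony):
        _, _, truth = noiseless_colony
        field = truth.noiseless["stable_reporter"]
        fracs = [profiles.fluorescent_fraction(field, truth.mask, t) for t in (0, 25, 50, 100, 150)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestFitDecayLength:
    def test_exact_exponential(self):
        d = np.arange(0.5, 40, 2.0)
        prof = ShellProfile(d, 100 * np.exp(-d / 20.0), np.full(d.size, 1000), 2.0)
        lam, r2 = profiles.fit_decay_length(prof, min_relative=0.0)
        assert lam == pytest.approx(20.0, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_flat_profile_raises(self):
        d = np.arange(0.5, 20, 2.0)
        prof = ShellProfile(d, np.full(d.size, 5.0), np.full(d.size, 1000), 2.0)
        with pytest.raises(ValueError):
            profiles.fit_decay_length(prof)

    def test_too_few_bins_raises(self):
        prof = ShellProfile(np.array([1.0, 3.0]), np.array([10.0, 5.0]), np.array([100, 100]), 2.0)
        with pytest.raises(ValueError):
            profiles.fit_decay_length(prof)

    def test_recovery_from_noisy_colonies(self, noisy_colonies):
        from colonymetrics import geometry

        for spec, image, _ in noisy_colonies:
            mask = geometry.segment_stack(image)
            dm = profiles.surface_distance_map(mask)
            stable = image.channel("stable_reporter")
            bg = profiles.estimate_background(stable, mask)
            lam, _ = profiles.fit_decay_length(profiles.shell_profile(stable - bg, dm))
            assert lam == pytest.approx(spec.lambda_decay, rel=0.10)
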