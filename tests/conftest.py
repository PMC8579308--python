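"""Shared fixtures: analytic solids and rendered synthetic colonies.

Everything is generated programmatically at test time; session scope keeps
the expensive renders to one per suite run.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from colonymetrics.synthetic import SyntheticColonySpec, render_colony

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from colonymetrics.types import ColonyMask, VoxelImage


def hemisphere_image(R: float = 50.0, voxel: float = 1.0, intensity: float = 200.0,
                     margin: float = 5.0) -> VoxelImage:
    """Noiseless hemisphere of radius R resting on the substrate."""
    n = int(math.ceil((2 * R + 2 * margin) / voxel))
    nz = int(math.ceil((R + margin) / voxel))
    c = n * voxel / 2.0
    x = (np.arange(n) + 0.5) * voxel - c
    r2 = x[None, :] ** 2 + x[:, None] ** 2
    zc = (np.arange(nz) + 0.5) * voxel
    mask = r2[None] + (zc**2)[:, None, None] < R * R
    return VoxelImage({"stable_reporter": np.where(mask, intensity, 0.0)}, (voxel, voxel, voxel))


def hemisphere_mask(R: float = 200.0, voxel: float = 1.0) -> ColonyMask:
    img = hemisphere_image(R=R, voxel=voxel)
    return ColonyMask(img.channel("stable_reporter") > 0, img.voxel_size)


def cone_mask(H: float = 200.0, R: float = 400.0, voxel: float = 1.0) -> ColonyMask:
    n = int(math.ceil((2 * R + 10) / voxel))
    nz = int(math.ceil((H + 5) / voxel))
    c = n * voxel / 2.0
    x = (np.arange(n) + 0.5) * voxel - c
    r = np.hypot(x[None, :], x[:, None])
    h = np.clip(H * (1 - r / R), 0.0, None)
    zc = (np.arange(nz) + 0.5) * voxel
    return ColonyMask(zc[:, None, None] < h[None], (voxel, voxel, voxel))


NOISELESS_KW = dict(poisson_on=False, read_sigma=0.0, background=0.0)


@pytest.fixture(scope="session")
def noiseless_colony():
    """Default-shape colony, noise off, fine lateral sampling."""
    spec = SyntheticColonySpec(voxel_size=(1.0, 1.0, 2.0), seed=11, **NOISELESS_KW)
    image, truth = render_colony(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_colonies():
    """Three replicate noisy renders of the default colony (seeds 1-3)."""
    out = []
    for seed in (1, 2, 3):
        spec = SyntheticColonySpec(voxel_size=(1.0, 1.0, 2.0), seed=seed)
        out.append((spec,) + render_colony(spec))
    return out


@pytest.fixture(scope="session")
def default_colony_coarse():
    """One noisy default-spec colony at the default 2 µm voxels (fast)."""
    spec = SyntheticColonySpec(seed=7)
    image, truth = render_colony(spec)
    return spec, image, truth
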