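"""Shared fixtures: analytic phantoms rasterized once per session."""

import numpy as np
import pytest

from vesselprox.volume_io import LabelVolume
from vesselprox.meshing import label_to_mesh
from vesselprox.phantoms import PhantomSpec, rasterize


def sphere_volume(radius, spacing=1.0, margin=3.0, center=None):
    """Binary sphere mask on an isotropic grid (voxel-center rasterization)."""
    sp = float(spacing)
    n = int(np.ceil((2 * radius + 2 * margin) / sp))
    ax = np.arange(n) * sp
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    if center is None:
        center = ((n - 1) * sp / 2,) * 3
    cx, cy, cz = center
    mask = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= radius**2
    return LabelVolume(mask.astype(np.uint8), (sp, sp, sp)), np.asarray(center, float)


def cylinder_volume(radius=4.0, length=60.0, spacing=1.0, center_xy=(16.0, 16.0), z0=4.0):
    """Axis-aligned (z) solid cylinder mask."""
    sp = float(spacing)
    nxy = int(np.ceil((center_xy[0] + radius + 4) / sp)) + 4
    nz = int(np.ceil((z0 + length + 4) / sp)) + 4
    ax = np.arange(nxy) * sp
    az = np.arange(nz) * sp
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    mask = ((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2 <= radius**2) & (Z >= z0) & (Z <= z0 + length)
    return LabelVolume(mask.astype(np.uint8), (sp, sp, sp))


@pytest.fixture(scope="session")
def sphere_r10():
    """r = 10 mm sphere at 1 mm spacing, with its center."""
    return sphere_volume(10.0, spacing=1.0)


@pytest.fixture(scope="session")
def sphere_r10_fine():
    """r = 10 mm sphere at 0.5 mm spacing (convergence checks)."""
    return sphere_volume(10.0, spacing=0.5)


@pytest.fixture(scope="session")
def sphere_r10_mesh(sphere_r10):
    vol, center = sphere_r10
    return label_to_mesh(vol), center


@pytest.fixture(scope="session")
def cylinder_r4_l60():
    """Straight cylinder r = 4 mm, length 60 mm along z, 1 mm grid."""
    return cylinder_volume()


@pytest.fixture(scope="session")
def tube_sphere_phantom():
    """Straight-tube vessel + lateral tumor sphere with analytic truth."""
    spec = PhantomSpec(
        shape=(96, 96, 96), spacing=(1.0, 1.0, 1.0),
        tumor_center=(58.0, 48.0, 48.0), tumor_radius=8.0,
        vessel_center_xy=(30.0, 48.0), vessel_radius=4.0,
        vessel_z_range=(10.0, 86.0),
    )
    tumor, vessel, truth = rasterize(spec)
    return spec, tumor, vessel, truth
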