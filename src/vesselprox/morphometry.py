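"""Tumor shape measures: volume, surface area, transverse-plane diameter.

Volume is voxel counting times voxel volume (the primary estimator; a
divergence-theorem mesh volume is provided as a cross-check).  Surface area
is the summed triangle area of the extracted mesh; because the raw binary
iso-surface carries a non-vanishing staircase area bias (~9% overestimate
on spheres, independent of resolution), :func:`tumor_metrics` measures area
on a Taubin-smoothed copy of the surface, which removes the bias while
moving vertices by well under a voxel.  The transverse-plane diameter TD is
the hypotenuse of the two transverse (left-right and anterior-posterior)
extents of the axis-aligned bounding box in world (patient) axes:
TD = sqrt(dx^2 + dy^2).  The box is axis-aligned in the patient frame —
not an oriented minimal box — because TD is defined in the transverse
plane of the box and must stay coupled to the anatomical axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import SurfaceMesh, label_to_mesh
from .volume_io import LabelVolume

__all__ = [
    "TumorMetrics",
    "tumor_volume",
    "surface_area",
    "mesh_volume",
    "bounding_box_extents",
    "transverse_diameter",
    "tumor_metrics",
]


@dataclass(frozen=True)
class TumorMetrics:
    """Shape summary of one tumor: volume (mm^3), surface area (mm^2),
    world-axis bounding-box extents (mm) and transverse diameter TD (mm)."""

    volume: float
    surface_area: float
    bbox_extents: tuple[float, float, float]
    td: float


def tumor_volume(vol: LabelVolume) -> float:
    """Foreground voxel count times voxel volume, in mm^3."""
    count = int(np.count_nonzero(vol.voxels))
    if count == 0:
        raise ValueError("empty mask: volume undefined")
    return count * vol.voxel_volume


def surface_area(mesh: SurfaceMesh) -> float:
    """Total mesh surface area in mm^2."""
    if mesh.n_faces == 0:
        raise ValueError("empty mesh: surface area undefined")
    return mesh.area()


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume of a closed mesh via the divergence theorem (mm^3).

    Cross-check estimator for :func:`tumor_volume`; requires a watertight
    mesh to be meaningful.
    """
    if mesh.n_faces == 0:
        raise ValueError("empty mesh: volume undefined")
    return float(abs(mesh.to_trimesh().volume))


def bounding_box_extents(obj: SurfaceMesh | LabelVolume) -> tuple[float, float, float]:
    """Axis-aligned bounding-box extents (dx, dy, dz) in world mm.

    For a mesh, extents come from vertex coordinates.  For a label volume,
    extents are the spread of foreground voxel centers plus the voxel
    footprint projected on each world axis (so a 30-voxel row at 1 mm
    spacing spans 30 mm, matching the 0.5 iso-surface of the mesh).
    """
    if isinstance(obj, SurfaceMesh):
        if obj.n_vertices == 0:
            raise ValueError("empty mesh")
        lo = obj.vertices.min(axis=0)
        hi = obj.vertices.max(axis=0)
        ext = hi - lo
    elif isinstance(obj, LabelVolume):
        idx = np.argwhere(obj.voxels > 0)
        if len(idx) == 0:
            raise ValueError("empty mask")
        world = np.asarray(obj.origin) + (idx * np.asarray(obj.spacing)) @ obj.direction.T
        footprint = (np.abs(obj.direction) * np.asarray(obj.spacing)).sum(axis=1)
        ext = world.max(axis=0) - world.min(axis=0) + footprint
    else:
        raise TypeError(f"expected SurfaceMesh or LabelVolume, got {type(obj).__name__}")
    return (float(ext[0]), float(ext[1]), float(ext[2]))


def transverse_diameter(obj: SurfaceMesh | LabelVolume) -> tuple[tuple[float, float, float], float]:
    """Bounding-box extents and transverse-plane diameter TD = hypot(dx, dy)."""
    ext = bounding_box_extents(obj)
    return ext, float(np.hypot(ext[0], ext[1]))


AREA_SMOOTHING_ITERATIONS = 10  # Taubin passes for the area-faithful surface


def tumor_metrics(vol: LabelVolume, area_mesh: SurfaceMesh | None = None) -> TumorMetrics:
    """All shape measures for one binary tumor volume.

    Volume comes from voxel counting; the bounding box (and TD) from the
    voxel footprint in world axes, which is exact for axis-aligned solids;
    surface area from a Taubin-smoothed iso-surface (extracted on the fly
    unless ``area_mesh`` is supplied), avoiding the staircase area bias of
    the raw binary marching-cubes surface.
    """
    if area_mesh is None:
        area_mesh = label_to_mesh(vol, smoothing_iterations=AREA_SMOOTHING_ITERATIONS)
    ext, td = transverse_diameter(vol)
    return TumorMetrics(
        volume=tumor_volume(vol),
        surface_area=surface_area(area_mesh),
        bbox_extents=ext,
        td=td,
    )
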