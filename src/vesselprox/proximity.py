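"""Minimum-distance fields between two surface meshes.

For every vertex of a source mesh (typically the vessel), the minimum
Euclidean distance to a target mesh (typically the tumor) is computed,
either to the nearest target *vertex* (``vertex-to-vertex``, the plain
point-cloud form v = sqrt((x1-x2)^2 + (y1-y2)^2 + (z1-z2)^2)) or to the
nearest point on any target *triangle* (``vertex-to-surface``, the default:
strictly more accurate, never larger).  The field's minimum is the
tumor-vessel clearance dTICA, and the vertex attaining it is the minimum
distance point (MDP).

Queries are accelerated with k-d trees but remain exact: for the
vertex-to-surface mode a per-vertex upper bound from the nearest target
vertex prunes candidate triangles, and any triangle that could beat the
bound necessarily has its centroid inside the search radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .meshing import SurfaceMesh, vertex_components

__all__ = ["DistanceField", "point_distance", "distance_field", "attach_heatmap"]

MODES = ("vertex-to-surface", "vertex-to-vertex")
_TIE_TOL = 1e-9  # mm; vertices within this of the minimum count as tied


@dataclass
class DistanceField:
    """Per-vertex minimum distances from a source mesh to a target mesh.

    ``dtica`` is the minimum of ``distances``; ``mdp_index`` the source
    vertex attaining it (lowest index on ties, all ties retained in
    ``mdp_tied_indices``); ``mdp_target_point`` the corresponding closest
    point on the target.  ``component_minima`` holds the minimum per
    face-connected source component (e.g. one value per vessel side).
    """

    source: SurfaceMesh
    distances: np.ndarray  # (n,) mm
    mode: str
    target_points: np.ndarray  # (n, 3) closest point on target per source vertex
    warn_on_contact: bool = True
    dtica: float = field(init=False)
    mdp_index: int = field(init=False)
    mdp_point: np.ndarray = field(init=False)
    mdp_target_point: np.ndarray = field(init=False)
    mdp_tied_indices: np.ndarray = field(init=False)
    component_minima: list[float] = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (self.source.n_vertices,):
            raise ValueError("distances length must match source vertex count")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.distances = d
        self.dtica = float(d.min())
        tied = np.flatnonzero(d <= self.dtica + _TIE_TOL)
        self.mdp_tied_indices = tied
        self.mdp_index = int(tied[0])
        self.mdp_point = self.source.vertices[self.mdp_index].copy()
        self.mdp_target_point = self.target_points[self.mdp_index].copy()
        labels = vertex_components(self.source)
        self.component_minima = [float(d[labels == c].min()) for c in range(labels.max() + 1)]
        if self.warn_on_contact and self.dtica <= _TIE_TOL:
            warnings.warn(
                "surfaces touch or intersect: minimum distance clamps at 0, "
                "penetration depth is not reported",
                stacklevel=3,
            )


def point_distance(p, q) -> float:
    """Euclidean distance (mm) between two world points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("points must have finite coordinates")
    return float(np.linalg.norm(p - q))


def _closest_on_surface(points: np.ndarray, target: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest point on the target triangulation for each query point.

    A k-d tree over target vertices gives an upper bound per query; a second
    tree over triangle centroids then returns every triangle whose closest
    point could lie within that bound (centroid within bound + triangle
    circumradius), and the exact point-triangle minimum is taken over those.
    """
    tri = target.triangles()
    centroids = tri.mean(axis=1)
    r_tri = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    r_max = float(r_tri.max())
    d_ub, _ = cKDTree(target.vertices).query(points)
    cent_tree = cKDTree(centroids)
    candidate_lists = cent_tree.query_ball_point(points, d_ub + r_max + 1e-9)
    dist = np.empty(len(points))
    closest = np.empty((len(points), 3))
    for i, (p, cand) in enumerate(zip(points, candidate_lists)):
        cand_tri = tri[cand] if cand else tri
        pts = trimesh.triangles.closest_point(cand_tri, np.broadcast_to(p, (len(cand), 3)))
        dd = np.linalg.norm(pts - p, axis=1)
        j = int(np.argmin(dd))
        dist[i] = dd[j]
        closest[i] = pts[j]
    return dist, closest


def distance_field(
    source: SurfaceMesh,
    target: SurfaceMesh,
    mode: str = "vertex-to-surface",
    warn_on_contact: bool = True,
) -> DistanceField:
    """Minimum distance from every source vertex to the target mesh.

    Parameters
    ----------
    source
        Mesh whose vertices receive distances (the heatmap carrier, e.g.
        the vessel surface).
    target
        Mesh measured against (e.g. the tumor surface).
    mode
        ``vertex-to-surface`` (default): distance to the nearest point on
        any target triangle.  ``vertex-to-vertex``: distance to the nearest
        target vertex, matching the plain point-cloud formulation.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("cannot compute distances to or from an empty mesh")
    if mode == "vertex-to-vertex" or target.n_faces == 0:
        d, idx = cKDTree(target.vertices).query(source.vertices)
        tpts = target.vertices[idx]
    else:
        d, tpts = _closest_on_surface(source.vertices, target)
    return DistanceField(source=source, distances=np.asarray(d, float), mode=mode,
                         target_points=np.asarray(tpts, float),
                         warn_on_contact=warn_on_contact)


def attach_heatmap(
    mesh: SurfaceMesh, dfield: DistanceField, channel: str = "distance_mm"
) -> SurfaceMesh:
    """Attach the per-vertex distances to the mesh as a named scalar channel.

    The field must have been computed on this mesh (vertex counts must
    match).  Files written afterwards (PLY/VTP) carry the channel, which
    renders as the distance heatmap.
    """
    if len(dfield.distances) != mesh.n_vertices:
        raise ValueError(
            f"field has {len(dfield.distances)} distances but mesh has "
            f"{mesh.n_vertices} vertices"
        )
    mesh.scalars[channel] = dfield.distances.copy()
    return mesh
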