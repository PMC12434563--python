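"""Deterministic synthetic phantoms with analytic ground truth.

Phantoms stand in for the clinical CT cohort: a tubular vessel (straight or
bent along a circular arc, mimicking the internal carotid artery from the
carotid bifurcation upward) and a spherical tumor placed at a controlled
surface-to-surface separation.  Every measured quantity — clearance dTICA,
MDP arc position along the vessel, tumor volume / surface area / transverse
diameter, and the centerline curve itself — is computed from the continuous
geometry, never from the rasterized voxels, so the measurement pipeline is
always tested against rasterization-independent truth.

The cohort generator emulates a staged study design: T1-T4 tumor stages,
n cases per stage, per-stage mean tumor-vessel separation following the
clinically observed trend (larger / higher-stage tumors sit closer to the
vessel) with truncated-normal case-to-case noise, and tumor radii growing
with stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .volume_io import LabelVolume

__all__ = ["PhantomSpec", "rasterize", "make_cohort", "DEFAULT_STAGE_SEPARATION_MM"]

# Per-stage mean tumor-vessel separation (mm) for T1..T4, following the
# observed clinical trend of higher-stage tumors lying closer to the artery.
DEFAULT_STAGE_SEPARATION_MM = (9.76, 7.49, 4.75, 4.80)
# Per-stage tumor radii (mm) chosen so that sphere volumes match the
# reported per-stage mean tumor volumes (~4.3, 5.6, 19.9, 27.1 cm^3).
DEFAULT_STAGE_RADIUS_MM = (10.1, 11.0, 16.8, 18.6)
MIN_SEPARATION_MM = 0.5  # truncation floor for the separation distribution
MARGIN_VOXELS = 2  # both structures must keep this margin to the grid edge


@dataclass
class PhantomSpec:
    """Generative parameters of one tumor + vessel phantom.

    The vessel is a tube of radius ``vessel_radius`` around a curve: a
    vertical straight line through ``vessel_center_xy`` spanning
    ``vessel_z_range``, or (``vessel_arc_radius`` set) a circular arc in
    the x-z plane bulging toward +x.  The tumor is a sphere.  ``truth()``
    returns analytic values for every quantity the pipeline measures.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center: tuple[float, float, float] = (60.0, 48.0, 48.0)
    tumor_radius: float = 10.0
    vessel_center_xy: tuple[float, float] = (30.0, 48.0)
    vessel_radius: float = 4.0
    vessel_z_range: tuple[float, float] = (10.0, 86.0)
    vessel_arc_radius: float | None = None  # None = straight tube
    allow_contact: bool = False
    seed: int = 0

    # -- continuous vessel curve ------------------------------------------

    def curve_point(self, t: float | np.ndarray) -> np.ndarray:
        """Vessel axis point at parameter t in [0, 1] (t=0 at the inferior end)."""
        t = np.asarray(t, dtype=float)
        z0, z1 = self.vessel_z_range
        cx, cy = self.vessel_center_xy
        z = z0 + t * (z1 - z0)
        if self.vessel_arc_radius is None:
            x = np.full_like(z, cx)
        else:
            # circular arc in the x-z plane through (cx, z0) and (cx, z1),
            # bulging toward +x with radius R >= (z1-z0)/2
            R = float(self.vessel_arc_radius)
            half = (z1 - z0) / 2.0
            if R < half:
                raise ValueError("vessel_arc_radius must be >= half the z-extent")
            zc = (z0 + z1) / 2.0
            xc = cx - np.sqrt(R**2 - half**2)
            x = xc + np.sqrt(R**2 - (z - zc) ** 2)
        y = np.full_like(z, cy)
        return np.stack([x, y, z], axis=-1)

    def curve_length(self, t: float = 1.0) -> float:
        """Arc length from the inferior end (t=0) to parameter t."""
        z0, z1 = self.vessel_z_range
        if self.vessel_arc_radius is None:
            return float(t * (z1 - z0))
        R = float(self.vessel_arc_radius)
        half = (z1 - z0) / 2.0
        zc = (z0 + z1) / 2.0
        z = z0 + t * (z1 - z0)
        # angle from arc center; length = R * swept angle
        a0 = np.arcsin((z0 - zc) / R)
        at = np.arcsin((z - zc) / R)
        return float(R * (at - a0))

    # -- analytic truths ---------------------------------------------------

    def _surface_clearance(self) -> tuple[float, float]:
        """(tumor-center distance to the vessel *surface*, argmin parameter t).

        The straight tube is a flat-capped cylinder (matching its
        rasterization), so the closest surface point may sit on the lateral
        wall, a flat cap, or the cap rim.  The arc tube's lateral surface is
        at ``vessel_radius`` from the curve; ``validate`` restricts arc
        phantoms to lateral closest approach, where this is exact.
        """
        c = np.asarray(self.tumor_center, dtype=float)
        rv = self.vessel_radius
        if self.vessel_arc_radius is None:
            cx, cy = self.vessel_center_xy
            z0, z1 = self.vessel_z_range
            rho = float(np.hypot(c[0] - cx, c[1] - cy))
            dz = max(z0 - c[2], c[2] - z1, 0.0)
            t = float(np.clip((c[2] - z0) / (z1 - z0), 0.0, 1.0))
            if dz == 0.0:
                return rho - rv, t  # beside the lateral wall (negative if inside)
            if rho <= rv:
                return dz, t  # above/below a flat cap
            return float(np.hypot(rho - rv, dz)), t  # beyond the cap rim
        res = minimize_scalar(
            lambda t: float(np.linalg.norm(c - self.curve_point(t))),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-9},
        )
        return float(res.fun) - rv, float(res.x)

    def truth(self) -> dict:
        """Analytic ground truth for every pipeline quantity (mm, mm^2, mm^3)."""
        surf_dist, t_min = self._surface_clearance()
        clearance = surf_dist - self.tumor_radius
        r = self.tumor_radius
        return {
            "dtica_mm": max(clearance, 0.0),
            "mdp_arc_mm": self.curve_length(t_min),
            "centerline_length_mm": self.curve_length(1.0),
            "volume_mm3": 4.0 / 3.0 * np.pi * r**3,
            "surface_area_mm2": 4.0 * np.pi * r**2,
            "td_mm": float(np.hypot(2 * r, 2 * r)),
            "bbox_extents_mm": (2 * r, 2 * r, 2 * r),
        }

    # -- validation --------------------------------------------------------

    def grid_extent(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def validate(self) -> None:
        margin = MARGIN_VOXELS * np.asarray(self.spacing)
        ext = self.grid_extent()
        c = np.asarray(self.tumor_center)
        r = self.tumor_radius
        if ((c - r) < margin).any() or ((c + r) > ext - margin).any():
            raise ValueError("tumor sphere exceeds grid (needs a 2-voxel margin)")
        ts = np.linspace(0, 1, 101)
        pts = self.curve_point(ts)
        rv = self.vessel_radius
        # lateral surface extends rv from the curve in x/y; the tube is cut
        # flat at the z-range ends, so z needs no radial allowance
        z0, z1 = self.vessel_z_range
        if (
            ((pts[:, :2] - rv) < margin[:2]).any()
            or ((pts[:, :2] + rv) > (ext[:2] - margin[:2])).any()
            or z0 < margin[2] or z1 > ext[2] - margin[2]
        ):
            raise ValueError("vessel tube exceeds grid (needs a 2-voxel margin)")
        if not self.allow_contact and self.truth()["dtica_mm"] <= 0.0:
            raise ValueError(
                "tumor and vessel overlap; set allow_contact=True if intended"
            )
        if self.vessel_arc_radius is not None:
            # arc tubes are cut flat at the z-range ends; the analytic
            # clearance (distance-to-curve minus radius) only holds when the
            # closest approach is lateral, away from the cut ends
            _, t_min = self._surface_clearance()
            if not 0.02 < t_min < 0.98:
                raise ValueError(
                    "tumor's closest approach is at an arc-tube end; analytic "
                    "clearance is only valid for lateral placement"
                )


def _voxel_center_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sp = np.asarray(spec.spacing)
    axes = [np.arange(n) * sp[a] for a, n in enumerate(spec.shape)]
    return np.meshgrid(*axes, indexing="ij")


def rasterize(spec: PhantomSpec) -> tuple[LabelVolume, LabelVolume, dict]:
    """Rasterize a phantom: voxel centers inside the continuous solid are foreground.

    Returns (tumor volume, vessel volume, analytic truth record).  Identity
    direction, origin at zero; rasterization is deterministic given the spec.
    """
    spec.validate()
    X, Y, Z = _voxel_center_grid(spec)
    cx, cy, cz = spec.tumor_center
    tumor = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) <= spec.tumor_radius**2

    if spec.vessel_arc_radius is None:
        vx, vy = spec.vessel_center_xy
        z0, z1 = spec.vessel_z_range
        vessel = (
            ((X - vx) ** 2 + (Y - vy) ** 2 <= spec.vessel_radius**2)
            & (Z >= z0) & (Z <= z1)
        )
    else:
        # distance to a dense polyline sample of the arc (0.05 mm steps:
        # chord error << rasterization error)
        n = max(int(np.ceil(spec.curve_length(1.0) / 0.05)), 2)
        samples = spec.curve_point(np.linspace(0.0, 1.0, n))
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        near = np.abs(pts[:, 2] - samples[:, 2].mean()) < (
            (spec.vessel_z_range[1] - spec.vessel_z_range[0]) / 2 + 2 * spec.vessel_radius
        )
        d = np.full(len(pts), np.inf)
        d[near], _ = cKDTree(samples).query(pts[near])
        z0, z1 = spec.vessel_z_range
        vessel = ((d <= spec.vessel_radius)
                  & (pts[:, 2] >= z0) & (pts[:, 2] <= z1)).reshape(spec.shape)

    kw = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0), direction=np.eye(3))
    return (
        LabelVolume(tumor.astype(np.uint8), **kw),
        LabelVolume(vessel.astype(np.uint8), **kw),
        spec.truth(),
    )


def make_cohort(
    n_per_stage: int = 15,
    seed: int = 0,
    stage_distance_means: tuple[float, ...] = DEFAULT_STAGE_SEPARATION_MM,
    noise_sd: float = 2.0,
    stage_tumor_radii: tuple[float, ...] = DEFAULT_STAGE_RADIUS_MM,
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[tuple[str, str, PhantomSpec]]:
    """Staged synthetic cohort: (case id, stage label, phantom spec) per case.

    Per-case separation is drawn from a normal with the stage's mean and
    ``noise_sd``, truncated at ``MIN_SEPARATION_MM``; tumor radius gets
    mild jitter around the stage radius.  Tumor height along the vessel is
    uniform.  All draws flow from one seeded generator, so the cohort is
    bit-reproducible.
    """
    if n_per_stage < 2:
        raise ValueError("n_per_stage must be >= 2")
    if len(stage_distance_means) != len(stage_tumor_radii):
        raise ValueError("one mean and one radius per stage required")
    if any(m <= 0 for m in stage_distance_means):
        raise ValueError("stage separation means must be positive")
    rng = np.random.default_rng(seed)
    ext = np.asarray(shape) * np.asarray(spacing)
    vx, vy = 30.0 * ext[0] / 96.0, ext[1] / 2.0
    z0, z1 = 10.0 * ext[2] / 96.0, ext[2] - 10.0 * ext[2] / 96.0
    vessel_radius = 4.0
    cases: list[tuple[str, str, PhantomSpec]] = []
    for s, (mean, radius) in enumerate(zip(stage_distance_means, stage_tumor_radii)):
        stage = f"T{s + 1}"
        for i in range(n_per_stage):
            if noise_sd > 0:
                a = (MIN_SEPARATION_MM - mean) / noise_sd
                sep = float(truncnorm.rvs(a, np.inf, loc=mean, scale=noise_sd,
                                          random_state=rng))
            else:
                sep = mean
            r = float(np.clip(radius + rng.normal(0.0, 0.5), 5.0, radius + 2.0))
            margin = (MARGIN_VOXELS + 0.5) * max(spacing)
            zc = float(rng.uniform(max(z0 + 5.0, r + margin),
                                   min(z1 - 5.0, ext[2] - r - margin)))
            cx = vx + vessel_radius + sep + r
            if cx + r + margin > ext[0]:
                raise ValueError(
                    f"stage {stage}: separation {sep:.1f} mm with radius {r:.1f} mm "
                    "does not fit on the grid"
                )
            spec = PhantomSpec(
                shape=tuple(shape), spacing=tuple(spacing),
                tumor_center=(cx, vy, zc), tumor_radius=r,
                vessel_center_xy=(vx, vy), vessel_radius=vessel_radius,
                vessel_z_range=(z0, z1),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            spec.validate()
            cases.append((f"{stage}-{i:03d}", stage, spec))
    return cases
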