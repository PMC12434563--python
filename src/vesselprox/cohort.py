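"""Per-case measurement orchestration and cohort-level statistics.

``run_case`` chains the full measurement pipeline for one subject: read the
label volumes, mesh both structures, compute the vessel-to-tumor distance
field (dTICA, MDP), extract the vessel centerline, localize the MDP as an
arc length from the carotid bifurcation, and collect tumor morphometrics.
Errors are re-raised with the pipeline stage and case id attached.

Cohort statistics mirror a staged observational analysis: one-way ANOVA of
each measure across tumor T stages, pairwise two-sample t-tests (equal
variance, two-sided, uncorrected by default — a Holm correction flag is
available), and Pearson correlation of each continuous measure with dTICA.
A paired t-test compares automatic against manual distance readings.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .centerline import extract_centerline, locate_bifurcation, mdp_arc_position
from .meshing import SurfaceMesh, label_to_mesh
from .morphometry import tumor_metrics
from .proximity import distance_field
from .volume_io import LabelVolume, read_label_volume, extract_label

__all__ = [
    "PipelineConfig",
    "CaseReport",
    "CohortStats",
    "run_case",
    "run_cohort",
    "stage_anova",
    "manual_vs_auto",
]

MEASURES = ("dtica_mm", "mdp_arc_mm", "volume_mm3", "surface_area_mm2", "td_mm")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the per-case pipeline.

    ``mode`` is the distance correspondence (vertex-to-surface default);
    ``smoothing_iterations`` applies Taubin smoothing to meshes before
    distance measurement (0 = off); ``centerline_smooth`` toggles the
    3-point moving average on the centerline polyline.
    """

    mode: str = "vertex-to-surface"
    smoothing_iterations: int = 0
    centerline_smooth: bool = True
    tumor_label: int = 1
    vessel_label: int = 1


@dataclass
class CaseReport:
    """All measured quantities for one case."""

    case_id: str
    stage: str  # "T1".."T4" or "unknown"
    dtica_mm: float
    mdp_arc_mm: float
    volume_mm3: float
    surface_area_mm2: float
    td_mm: float
    mdp_point: tuple[float, float, float]
    per_side_min_mm: list[float] = dc_field(default_factory=list)
    warnings: list[str] = dc_field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "stage": self.stage,
            "dtica_mm": self.dtica_mm,
            "mdp_arc_mm": self.mdp_arc_mm,
            "volume_mm3": self.volume_mm3,
            "surface_area_mm2": self.surface_area_mm2,
            "td_mm": self.td_mm,
        }
        for i, v in enumerate(self.per_side_min_mm):
            row[f"side{i}_min_mm"] = v
        row["warnings"] = ";".join(self.warnings)
        return row


class PipelineError(RuntimeError):
    """Pipeline failure carrying the stage name and case id."""

    def __init__(self, case_id: str, stage: str, cause: Exception):
        super().__init__(f"case {case_id!r}, stage {stage!r}: {cause}")
        self.case_id = case_id
        self.stage = stage
        self.__cause__ = cause


def _binary(vol: LabelVolume, label: int) -> LabelVolume:
    labels = vol.labels_present()
    if labels == [1] or label in labels:
        return extract_label(vol, label if label in labels else 1)
    raise ValueError(f"label {label} absent; labels present: {labels}")


def run_case(
    tumor: str | LabelVolume,
    vessel: str | LabelVolume,
    fiducial=None,
    config: PipelineConfig = PipelineConfig(),
    case_id: str = "case",
    stage: str = "unknown",
) -> CaseReport:
    """Run the full measurement pipeline for one tumor-vessel pair.

    ``tumor`` and ``vessel`` may be file paths (NIfTI/NRRD) or in-memory
    label volumes.  The distance field is carried on the vessel surface
    (the heatmap side); the centerline is extracted from the vessel
    component containing the MDP when the vessel mask is bilateral.
    """
    notes: list[str] = []

    def _stage(name, fn, *args, **kw):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                out = fn(*args, **kw)
            notes.extend(f"{name}: {w.message}" for w in caught)
            return out
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(case_id, name, exc) from exc

    if isinstance(tumor, (str, bytes)) or hasattr(tumor, "__fspath__"):
        tumor = _stage("read_tumor", read_label_volume, tumor)
    if isinstance(vessel, (str, bytes)) or hasattr(vessel, "__fspath__"):
        vessel = _stage("read_vessel", read_label_volume, vessel)
    tumor_mask = _stage("extract_tumor_label", _binary, tumor, config.tumor_label)
    vessel_mask = _stage("extract_vessel_label", _binary, vessel, config.vessel_label)

    tumor_mesh = _stage("mesh_tumor", label_to_mesh, tumor_mask, config.smoothing_iterations)
    vessel_mesh = _stage("mesh_vessel", label_to_mesh, vessel_mask, config.smoothing_iterations)

    dfield = _stage("distance_field", distance_field, vessel_mesh, tumor_mesh, config.mode)

    # centerline on the vessel component containing the MDP (bilateral masks)
    def _centerline_side():
        lab, n = ndimage.label(vessel_mask.voxels)
        if n > 1:
            idx = np.round(
                (vessel_mask.direction.T @ (dfield.mdp_point - np.asarray(vessel_mask.origin)))
                / np.asarray(vessel_mask.spacing)
            ).astype(int)
            idx = np.clip(idx, 0, np.asarray(vessel_mask.shape) - 1)
            side = lab[tuple(idx)]
            if side == 0:  # MDP vertex sits on the iso-surface; probe its neighborhood
                fg = np.argwhere(lab > 0)
                side = lab[tuple(fg[np.argmin(np.abs(fg - idx).sum(axis=1))])]
            mask = LabelVolume((lab == side).astype(np.uint8), vessel_mask.spacing,
                               vessel_mask.origin, vessel_mask.direction.copy())
        else:
            mask = vessel_mask
        return extract_centerline(mask, smooth=config.centerline_smooth)

    cl = _stage("centerline", _centerline_side)
    cl = _stage("locate_bifurcation", locate_bifurcation, cl, fiducial)
    arc = _stage("mdp_arc_position", mdp_arc_position, cl, dfield.mdp_point)

    metrics = _stage("morphometry", tumor_metrics, tumor_mask)

    return CaseReport(
        case_id=case_id,
        stage=stage,
        dtica_mm=dfield.dtica,
        mdp_arc_mm=arc,
        volume_mm3=metrics.volume,
        surface_area_mm2=metrics.surface_area,
        td_mm=metrics.td,
        mdp_point=tuple(float(v) for v in dfield.mdp_point),
        per_side_min_mm=list(dfield.component_minima),
        warnings=notes,
    )


def run_cohort(
    manifest: pd.DataFrame | str,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Run every case of a manifest and return the per-case report table.

    The manifest needs columns ``case_id``, ``tumor_path``, ``vessel_path``
    and optionally ``stage`` and ``fiducial_x/y/z_mm``.  Row order is
    preserved; output is deterministic given inputs and config.
    """
    if isinstance(manifest, (str, bytes)) or hasattr(manifest, "__fspath__"):
        manifest = pd.read_csv(manifest)
    required = {"case_id", "tumor_path", "vessel_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for rec in manifest.to_dict("records"):
        fid = None
        if {"fiducial_x_mm", "fiducial_y_mm", "fiducial_z_mm"} <= set(rec) and \
                np.isfinite([rec["fiducial_x_mm"], rec["fiducial_y_mm"], rec["fiducial_z_mm"]]).all():
            fid = (rec["fiducial_x_mm"], rec["fiducial_y_mm"], rec["fiducial_z_mm"])
        report = run_case(
            rec["tumor_path"], rec["vessel_path"], fiducial=fid, config=config,
            case_id=str(rec["case_id"]), stage=str(rec.get("stage", "unknown")),
        )
        rows.append(report.to_row())
    return pd.DataFrame(rows)


@dataclass
class CohortStats:
    """Stage-wise summary, ANOVA and pairwise t-test p-values, and Pearson
    correlations of each measure with dTICA (alpha = 0.05 convention)."""

    group_means: pd.DataFrame  # stage x measure
    group_sds: pd.DataFrame
    anova_p: dict[str, float]
    anova_f: dict[str, float]
    pairwise_p: dict[str, pd.DataFrame]  # measure -> stage x stage matrix
    pearson_r: dict[str, float]  # measure (vs dtica) -> r
    pearson_r2: dict[str, float]
    alpha: float = 0.05


def stage_anova(
    table: pd.DataFrame,
    measures: tuple[str, ...] = MEASURES,
    stage_col: str = "stage",
    holm: bool = False,
) -> CohortStats:
    """One-way fixed-effects ANOVA and pairwise t-tests per measure across stages.

    Pairwise tests are two-sided equal-variance two-sample t-tests,
    uncorrected unless ``holm`` is set (Holm step-down over each measure's
    pairwise family).  Pearson r (and r^2) is computed between each other
    measure and dTICA.
    """
    measures = tuple(m for m in measures if m in table.columns)
    stages = sorted(table[stage_col].dropna().unique())
    if len(stages) < 2:
        raise ValueError("need at least two stage groups")
    groups = {s: table[table[stage_col] == s] for s in stages}
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("each stage group needs at least two observations")

    means = pd.DataFrame({m: {s: groups[s][m].mean() for s in stages} for m in measures})
    sds = pd.DataFrame({m: {s: groups[s][m].std(ddof=1) for s in stages} for m in measures})

    anova_p: dict[str, float] = {}
    anova_f: dict[str, float] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    for m in measures:
        samples = [groups[s][m].to_numpy(float) for s in stages]
        if np.ptp(np.concatenate(samples)) == 0:
            raise ValueError(f"measure {m!r} has zero variance overall")
        f, p = stats.f_oneway(*samples)
        anova_f[m] = float(f)
        anova_p[m] = float(p)
        mat = pd.DataFrame(np.nan, index=stages, columns=stages)
        pairs = list(itertools.combinations(range(len(stages)), 2))
        pvals = []
        for i, j in pairs:
            pvals.append(float(stats.ttest_ind(samples[i], samples[j], equal_var=True).pvalue))
        if holm:
            order = np.argsort(pvals)
            adj = np.empty(len(pvals))
            running = 0.0
            for rank, oi in enumerate(order):
                running = max(running, (len(pvals) - rank) * pvals[oi])
                adj[oi] = min(running, 1.0)
            pvals = list(adj)
        for (i, j), p_ij in zip(pairs, pvals):
            mat.iloc[i, j] = p_ij
            mat.iloc[j, i] = p_ij
        pairwise[m] = mat

    pearson_r: dict[str, float] = {}
    pearson_r2: dict[str, float] = {}
    if "dtica_mm" in table.columns:
        for m in measures:
            if m == "dtica_mm":
                continue
            r = float(stats.pearsonr(table[m], table["dtica_mm"]).statistic)
            pearson_r[m] = r
            pearson_r2[m] = r * r

    return CohortStats(
        group_means=means, group_sds=sds, anova_p=anova_p, anova_f=anova_f,
        pairwise_p=pairwise, pearson_r=pearson_r, pearson_r2=pearson_r2,
    )


def manual_vs_auto(auto, manual) -> tuple[float, float]:
    """Paired comparison of automatic vs manual distance readings.

    Returns (mean difference auto - manual in mm, two-sided paired t-test
    p-value).
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be equal-length 1D sequences")
    diff = auto - manual
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        # constant difference: t-test degenerate; p = 1 when the constant is 0
        p = 1.0 if abs(mean_diff) < 1e-12 else 0.0
    else:
        p = float(stats.ttest_rel(auto, manual).pvalue)
    return mean_diff, p
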