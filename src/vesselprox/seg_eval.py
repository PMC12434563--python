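"""Segmentation evaluation: Dice similarity coefficient and average Hausdorff distance.

DSC is volumetric: 2|A∩B| / (|A| + |B|) over foreground voxels of two masks
on the same grid (1 = perfect overlap).  AHD is a surface error: the mean
distance in mm from each reference surface point to its closest point on
the compared surface.  The directed form (reference -> prediction) is the
default, matching the usual ground-truth-anchored definition; a symmetric
variant (mean of the two directed values) is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import SurfaceMesh, label_to_mesh
from .proximity import distance_field
from .volume_io import LabelVolume

__all__ = ["EvalResult", "dice", "average_hausdorff", "evaluate_segmentation"]


@dataclass(frozen=True)
class EvalResult:
    """DSC plus directed (reference->prediction) and symmetric AHD in mm."""

    dsc: float
    ahd_directed: float
    ahd_symmetric: float


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Volumetric Dice coefficient of two binary masks on an identical grid.

    Raises
    ------
    ValueError
        If the grids differ (beyond 1e-6 metadata jitter — no silent
        resampling) or both masks are empty (undefined).
    """
    if not a.same_grid(b):
        raise ValueError(
            "grid mismatch: masks must share shape, spacing, origin and "
            "direction (within 1e-6) — resample explicitly first"
        )
    fa = a.voxels > 0
    fb = b.voxels > 0
    na = int(fa.sum())
    nb = int(fb.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 2.0 * int((fa & fb).sum()) / (na + nb)


def average_hausdorff(
    reference: SurfaceMesh,
    predicted: SurfaceMesh,
    directed: bool = True,
    mode: str = "vertex-to-surface",
) -> float:
    """Average Hausdorff distance between two surface meshes, in mm.

    Directed (default): mean over reference vertices of the distance to the
    nearest point of the predicted surface.  Symmetric: mean of the two
    directed values.  ``mode`` selects vertex or surface correspondence,
    shared with the proximity heatmap machinery.
    """
    fwd = float(distance_field(reference, predicted, mode=mode, warn_on_contact=False).distances.mean())
    if directed:
        return fwd
    bwd = float(distance_field(predicted, reference, mode=mode, warn_on_contact=False).distances.mean())
    return 0.5 * (fwd + bwd)


def evaluate_segmentation(
    reference: LabelVolume, predicted: LabelVolume, mode: str = "vertex-to-surface"
) -> EvalResult:
    """DSC and AHD of a predicted mask against a reference mask.

    Surfaces are extracted at the 0.5 iso-level without smoothing; both
    directed and symmetric AHD are reported.
    """
    d = dice(reference, predicted)
    mref = label_to_mesh(reference)
    mpred = label_to_mesh(predicted)
    fwd = float(distance_field(mref, mpred, mode=mode, warn_on_contact=False).distances.mean())
    bwd = float(distance_field(mpred, mref, mode=mode, warn_on_contact=False).distances.mean())
    return EvalResult(dsc=d, ahd_directed=fwd, ahd_symmetric=0.5 * (fwd + bwd))
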