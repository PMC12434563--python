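"""Reading and writing segmentation label volumes with physical-space metadata.

The in-memory container is :class:`LabelVolume`: an integer voxel grid plus
spacing (mm), origin (mm) and a 3x3 orthonormal direction matrix.  The world
frame is LPS (left-posterior-superior), the native frame of ITK; NIfTI files
(whose on-disk affine is RAS) are converted on read by SimpleITK.  Voxel
indices are 0-based and refer to voxel *centers*, matching the vertex
placement of the marching-cubes surface extraction downstream.

The voxel array is stored index-ordered ``voxels[i, j, k]`` where (i, j, k)
is the ITK index -- i.e. axis 0 advances along the first physical axis, not
the NumPy-from-file slowest axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "LabelVolume",
    "read_label_volume",
    "write_label_volume",
    "extract_label",
    "voxel_to_world",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".nrrd", ".nhdr", ".mha", ".mhd")


@dataclass
class LabelVolume:
    """A 3D integer label map in physical space.

    Attributes
    ----------
    voxels
        3D integer array of label ids; 0 is background.  Index order is
        (i, j, k) along the three physical axes.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World coordinate (mm, LPS) of voxel center (0, 0, 0).
    direction
        3x3 orthonormal matrix whose columns are the world directions of
        the three index axes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.allclose(self.voxels, rounded, atol=1e-6):
                raise ValueError("voxels must be integer-valued")
            self.voxels = rounded.astype(np.int32)
        if self.voxels.min() < 0:
            raise ValueError("voxels must be non-negative label ids")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-6 or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-6
        ):
            raise ValueError("direction matrix is not orthonormal (|det| must be 1 within 1e-6)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal(self) -> float:
        """Length of the voxel body diagonal in mm (discretization scale)."""
        return float(np.linalg.norm(self.spacing))

    def labels_present(self) -> list[int]:
        return [int(v) for v in np.unique(self.voxels) if v != 0]

    def same_grid(self, other: "LabelVolume", atol: float = 1e-6) -> bool:
        """True if both volumes live on the same grid within ``atol``."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


def _check_path(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    low = path.lower()
    if not any(low.endswith(ext) for ext in _SUPPORTED_EXT):
        raise ValueError(f"unsupported file format: {path!r} (expected one of {_SUPPORTED_EXT})")
    return path


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read a NIfTI or NRRD label map into a :class:`LabelVolume`.

    Metadata is mapped to world mm in the LPS frame.  The voxel array is
    transposed from the file's (k, j, i) layout to index order (i, j, k).

    Raises
    ------
    ValueError
        If the image is not 3D, not integer-valued, or its direction
        matrix is not orthonormal.
    """
    path = _check_path(path)
    img = sitk.ReadImage(path)
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"expected a 3D scalar volume, got {img.GetDimension()}D with "
            f"{img.GetNumberOfComponentsPerPixel()} components: {path!r}"
        )
    arr = sitk.GetArrayFromImage(img)  # (k, j, i)
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return LabelVolume(
        voxels=voxels,
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        direction=direction,
    )


def write_label_volume(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a :class:`LabelVolume` to NIfTI or NRRD (by file extension)."""
    path = os.fspath(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)).astype(np.uint16))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(tuple(vol.direction.ravel()))
    sitk.WriteImage(img, path)


def extract_label(vol: LabelVolume, label_id: int) -> LabelVolume:
    """Binary mask (0/1) of one label, metadata preserved.

    Raises
    ------
    ValueError
        If ``label_id`` is not positive or absent from the volume; the
        error message lists the labels that are present.
    """
    label_id = int(label_id)
    if label_id <= 0:
        raise ValueError(f"label_id must be positive, got {label_id}")
    mask = (vol.voxels == label_id)
    if not mask.any():
        raise ValueError(
            f"label {label_id} absent from volume; labels present: {vol.labels_present()}"
        )
    return LabelVolume(
        voxels=mask.astype(np.uint8),
        spacing=vol.spacing,
        origin=vol.origin,
        direction=vol.direction.copy(),
    )


def voxel_to_world(vol: LabelVolume, index) -> np.ndarray:
    """World coordinate (mm) of a voxel center: origin + direction @ (spacing * index).

    ``index`` may be a single (i, j, k) triple or an (n, 3) array of triples;
    indices are 0-based and must lie within the grid.
    """
    idx = np.asarray(index, dtype=float)
    single = idx.ndim == 1
    idx = np.atleast_2d(idx)
    if idx.shape[1] != 3:
        raise ValueError("index must be an (i, j, k) triple")
    shape = np.asarray(vol.shape)
    if (idx < 0).any() or (idx > shape - 1).any():
        raise IndexError(f"index out of bounds for grid of shape {vol.shape}")
    world = np.asarray(vol.origin) + (idx * np.asarray(vol.spacing)) @ vol.direction.T
    return world[0] if single else world
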