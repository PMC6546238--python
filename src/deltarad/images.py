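"""In-memory containers for volumetric images and regions of interest.

The world-coordinate convention used throughout the package: voxel indices
are 0-based and the center of voxel ``(i, j, k)`` sits at
``origin + index * spacing`` (no direction matrix; axes are axis-aligned).
Array axis order is ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Allowed modality tags for an ImageVolume.
MODALITIES = ("CT", "PET-activity", "PET-SUV")

#: 3x3x3 structuring element giving 26-connectivity in 3D.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm), origin (mm) and a modality tag.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar voxel values (HU for CT, kBq/mL for PET-activity, unitless
        for PET-SUV).
    spacing : tuple of float
        Voxel spacing in mm along (x, y, z); strictly positive.
    origin : tuple of float
        World coordinate of the center of voxel (0, 0, 0), in mm.
    modality : str
        One of :data:`MODALITIES`.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        if any(n < 2 for n in self.values.shape):
            raise ValueError("each dimension must have at least 2 voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ImageVolume":
        """Copy of this volume with new voxel values (same geometry)."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       modality=modality or self.modality)


@dataclass
class RoiMask:
    """A binary 3D grid aligned to an :class:`ImageVolume`.

    ``n_components`` counts 26-connected foreground components and is
    recomputed whenever the voxel grid changes.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("RoiMask requires a 3D array")
        if not self.values.any():
            raise ValueError("RoiMask must be nonempty")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in self.origin)
        _, self.n_components = ndimage.label(self.values, structure=STRUCT_26)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """Total mask volume: voxel count times voxel volume."""
        return float(self.values.sum()) * self.voxel_volume


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(img: ImageVolume | RoiMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 with spacing/origin in the affine."""
    data = img.values.astype(np.float32 if isinstance(img, ImageVolume) else np.uint8)
    nii = nib.Nifti1Image(data, _affine(img.spacing, img.origin))
    nii.header.set_zooms(img.spacing)
    nib.save(nii, str(path))


def load_nifti(path: str | Path, modality: str = "CT") -> ImageVolume:
    nii = nib.load(str(path))
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(v) for v in nii.affine[:3, 3])
    return ImageVolume(np.asanyarray(nii.dataobj), spacing, origin, modality)


def load_nifti_mask(path: str | Path) -> RoiMask:
    nii = nib.load(str(path))
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(v) for v in nii.affine[:3, 3])
    return RoiMask(np.asanyarray(nii.dataobj) > 0.5, spacing, origin)
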