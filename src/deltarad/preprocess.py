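"""PET SUV conversion, resampling to common voxel grids, and ROI checks.

All images are resampled to common voxel dimensions before feature
extraction (defaults: 1x1x3 mm for CT, 4x4x3 mm for PET) using cubic
interpolation in world coordinates. Masks travel through the same
interpolation pathway and are re-binarized at 0.5; a mask that splits into
more than one 26-connected component after resampling disqualifies the
patient (tracked, never silently dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ImageVolume, RoiMask

logger = logging.getLogger(__name__)

#: Common voxel grids used for feature extraction, in mm.
CT_TARGET_SPACING = (1.0, 1.0, 3.0)
PET_TARGET_SPACING = (4.0, 4.0, 3.0)

#: F-18 half-life in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class SuvParams:
    """Quantities needed for body-weight SUV normalization.

    injected_dose is in MBq, body_weight in kg, delay_minutes the time
    between tracer injection and image acquisition.
    """

    injected_dose: float
    body_weight: float
    delay_minutes: float = 60.0
    half_life_minutes: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_dose", "body_weight", "half_life_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delay_minutes < 0:
            raise ValueError("delay_minutes must be nonnegative")


def to_suv(img: ImageVolume, p: SuvParams) -> ImageVolume:
    """Convert a PET activity-concentration image (kBq/mL) to SUV (body weight).

    SUV(v) = C(v) * body_weight[g] / (dose[kBq] * 2^(-delay / half_life)),
    i.e. the injected dose is decay-corrected to acquisition time. With
    tissue density taken as 1 g/mL, SUV is unitless.
    """
    if img.modality != "PET-activity":
        raise ValueError("to_suv expects a PET-activity image in kBq/mL")
    dose_kbq = p.injected_dose * 1000.0
    weight_g = p.body_weight * 1000.0
    decay = 2.0 ** (-p.delay_minutes / p.half_life_minutes)
    return img.with_values(img.values * weight_g / (dose_kbq * decay),
                           modality="PET-SUV")


def _target_shape(shape, spacing, target_spacing) -> tuple[int, ...]:
    # Preserve world-space extent to within one voxel.
    return tuple(max(2, int(round(n * s / t)))
                 for n, s, t in zip(shape, spacing, target_spacing))


def _resample_array(values: np.ndarray, spacing, target_spacing,
                    order: int = 3) -> np.ndarray:
    new_shape = _target_shape(values.shape, spacing, target_spacing)
    # voxel centers at origin + index*spacing: new center index*t maps to
    # fractional old index index*t/s along each axis
    grids = [np.arange(n) * t / s for n, t, s in
             zip(new_shape, target_spacing, spacing)]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(values, coords, order=order,
                                   mode="nearest")


def resample(img: ImageVolume, target_spacing) -> ImageVolume:
    """Resample onto the target spacing with tricubic spline interpolation.

    Out-of-grid samples use nearest-edge padding. Resampling to the
    image's own spacing is the identity.
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    if target_spacing == img.spacing:
        return img
    out = _resample_array(img.values, img.spacing, target_spacing)
    return ImageVolume(out, target_spacing, img.origin, img.modality)


def resample_mask(mask: RoiMask, target_spacing) -> RoiMask:
    """Resample a binary mask via the scalar pathway, re-binarized at 0.5.

    The mask is interpolated exactly like an image (cubic) and thresholded,
    so resampling artifacts that would split a thin segment show up here the
    same way they do in the intensity channel. Raises if the result is empty.
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    if target_spacing == mask.spacing:
        return mask
    field = _resample_array(mask.values.astype(np.float64), mask.spacing,
                            target_spacing)
    binary = field >= 0.5
    if not binary.any():
        raise ValueError("mask is empty after resampling")
    return RoiMask(binary, target_spacing, mask.origin)


def check_single_segment(mask: RoiMask, patient_id: str | None = None) -> bool:
    """Accept a mask iff it is a single 26-connected segment.

    A mask that split into multiple segments during resampling makes the
    texture features ill-defined, so the patient is excluded; every
    rejection is logged with the patient id.
    """
    ok = mask.n_components == 1
    if not ok:
        logger.warning(
            "mask for patient %s has %d segments; patient excluded",
            patient_id if patient_id is not None else "<unknown>",
            mask.n_components,
        )
    return ok
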