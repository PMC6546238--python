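"""Full per-image feature extraction and feature-table assembly.

``extract_all`` runs every enabled feature group on one (image, mask)
pair and returns a :class:`FeatureVector` with deterministic ordering.
Feature names follow ``filter_family_statistic`` (e.g.
``wavelet-LLH_GLSZM_inverse-variance``); unfiltered features carry no
filter prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import DEFAULT_CT, DEFAULT_PET, DiscretizationConfig
from .featurevector import FeatureVector
from .features import (fractal_features, intensity_histogram_features,
                       ivh_features, local_intensity_features, shape_features,
                       statistical_features)
from .filters import DEFAULT_LOG_SIGMAS_MM, log_filter, wavelet_filter
from .images import ImageVolume, RoiMask
from .texture import TEXTURE_KINDS, build_texture_matrix, texture_features


@dataclass(frozen=True)
class ExtractionConfig:
    """Which feature groups run, and with what settings."""

    disc_ct: DiscretizationConfig = DEFAULT_CT
    disc_pet: DiscretizationConfig = DEFAULT_PET
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    wavelet: str = "coif1"
    texture_aggregation: str = "merged-3D-directions"
    families: tuple[str, ...] = ("shape", "fractal", "local-intensity",
                                 "stats", "intensity-histogram", "ivh",
                                 "texture", "log", "wavelet")
    texture_kinds: tuple[str, ...] = TEXTURE_KINDS
    wavelet_texture_kinds: tuple[str, ...] = TEXTURE_KINDS


#: A light configuration for large simulation studies: original-image
#: groups only (no filtered variants).
FAST_CONFIG = ExtractionConfig(families=("shape", "stats",
                                         "intensity-histogram", "ivh",
                                         "texture"))


def _crop_to_roi(img: ImageVolume, mask: RoiMask, margin: int = 1):
    """Crop image and mask to the ROI bounding box plus a margin.

    Texture matrices only see ROI voxels and their immediate neighbors, so
    this is a pure speed optimization for those families.
    """
    coords = np.argwhere(mask.values)
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + margin, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_img = ImageVolume(img.values[sl], img.spacing, img.origin, img.modality)
    sub_mask = RoiMask(mask.values[sl], mask.spacing, mask.origin)
    return sub_img, sub_mask


def _texture_block(img: ImageVolume, mask: RoiMask, disc, cfg,
                   kinds) -> FeatureVector:
    fv = FeatureVector()
    for kind in kinds:
        tm = build_texture_matrix(img, mask, disc, kind,
                                  aggregation=cfg.texture_aggregation)
        fv.update(texture_features(tm), prefix=f"{kind}_")
    return fv


def extract_all(img: ImageVolume, mask: RoiMask,
                config: ExtractionConfig = ExtractionConfig()) -> FeatureVector:
    """Extract the configured feature inventory from one image/mask pair.

    The IVH group runs on PET-SUV images only; all other groups run on
    both modalities. Filtered variants re-run the group the filter feeds:
    LoG feeds first-order statistics, the wavelet sub-bands feed texture.
    """
    is_pet = img.modality == "PET-SUV"
    disc = config.disc_pet if is_pet else config.disc_ct
    fv = FeatureVector()
    fams = config.families
    if "shape" in fams:
        fv.update(shape_features(mask), prefix="shape_")
    if "fractal" in fams:
        fv.update(fractal_features(img, mask), prefix="fractal_")
    if "local-intensity" in fams:
        fv.update(local_intensity_features(img, mask), prefix="locint_")
    if "stats" in fams:
        fv.update(statistical_features(img, mask), prefix="stats_")
    if "intensity-histogram" in fams:
        fv.update(intensity_histogram_features(img, mask, disc),
                  prefix="inthist_")
    if "ivh" in fams and is_pet:
        _, ivh_fv = ivh_features(img, mask)
        fv.update(ivh_fv, prefix="ivh_")
    sub_img, sub_mask = _crop_to_roi(img, mask)
    if "texture" in fams:
        fv.update(_texture_block(sub_img, sub_mask, disc, config,
                                 config.texture_kinds))
    if "log" in fams:
        for name, filtered in log_filter(img, config.log_sigmas_mm).items():
            fv.update(statistical_features(filtered, mask),
                      prefix=f"{name}_stats_")
    if "wavelet" in fams:
        wb = wavelet_filter(sub_img, config.wavelet)
        for label, band in wb.bands.items():
            fv.update(_texture_block(band, sub_mask, disc, config,
                                     config.wavelet_texture_kinds),
                      prefix=f"wavelet-{label}_")
    return fv


@dataclass
class FeatureTable:
    """Patients x features matrix with provenance tags.

    ``data`` is indexed by patient id; ``modality``/``time_point`` tag the
    image set the rows came from.
    """

    data: pd.DataFrame
    modality: str = ""
    time_point: str = ""
    missing_reasons: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_vectors(cls, vectors: dict[str, FeatureVector],
                     modality: str = "", time_point: str = "") -> "FeatureTable":
        rows = {pid: fv.as_dict() for pid, fv in vectors.items()}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "patient_id"
        reasons = {pid: dict(fv.missing) for pid, fv in vectors.items()
                   if fv.missing}
        return cls(df.sort_index(), modality, time_point, reasons)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)
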