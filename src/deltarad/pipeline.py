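"""End-to-end wiring: preprocess patients and build the eight image-set
feature tables (per-time-point features plus absolute/relative deltas)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delta import IMAGE_SET_LABELS, delta_abs, delta_rel
from .extract import ExtractionConfig, FeatureTable, extract_all
from .featurevector import FeatureVector
from .images import ImageVolume, RoiMask
from .preprocess import (CT_TARGET_SPACING, PET_TARGET_SPACING,
                         check_single_segment, resample, _resample_array)
from .synthetic import SyntheticPatient

logger = logging.getLogger(__name__)


def resample_mask_like(mask: RoiMask, ref: ImageVolume) -> RoiMask:
    """Resample a mask onto a reference image's exact grid (0.5 threshold)."""
    if mask.spacing == ref.spacing and mask.shape == ref.shape:
        return mask
    grids = [np.arange(n) * t / s for n, t, s in
             zip(ref.shape, ref.spacing, mask.spacing)]
    coords = np.meshgrid(*grids, indexing="ij")
    from scipy import ndimage
    field = ndimage.map_coordinates(mask.values.astype(np.float64), coords,
                                    order=3, mode="nearest")
    binary = field >= 0.5
    if not binary.any():
        raise ValueError("mask is empty after resampling")
    return RoiMask(binary, ref.spacing, ref.origin)


@dataclass
class PreprocessedPatient:
    patient_id: str
    cohort: str
    images: dict[tuple[str, str], ImageVolume]   # (modality, timepoint)
    masks: dict[tuple[str, str], RoiMask]


def preprocess_patient(p: SyntheticPatient,
                       ct_target=CT_TARGET_SPACING,
                       pet_target=PET_TARGET_SPACING) -> PreprocessedPatient | None:
    """Resample all four volumes to the common grids and align the masks.

    Returns None (and logs) when any resampled mask violates the
    single-segment rule — the patient is excluded, mirroring clinical QA.
    """
    images, masks = {}, {}
    for modality, target in (("CT", ct_target), ("PET", pet_target)):
        for tp, img_name, mask_name in (("scan1", "pre", "mask_pre"),
                                        ("scan2", "during", "mask_during")):
            attr = f"{'ct' if modality == 'CT' else 'pet'}_{img_name}"
            img = resample(getattr(p, attr), target)
            mask = resample_mask_like(getattr(p, mask_name), img)
            if not check_single_segment(mask, patient_id=p.patient_id):
                return None
            images[(modality, tp)] = img
            masks[(modality, tp)] = mask
    return PreprocessedPatient(p.patient_id, p.cohort, images, masks)


def extract_patient(prep: PreprocessedPatient,
                    config: ExtractionConfig) -> dict[tuple[str, str], FeatureVector]:
    return {key: extract_all(prep.images[key], prep.masks[key], config)
            for key in prep.images}


def build_image_set_tables(patients: list[SyntheticPatient],
                           config: ExtractionConfig = ExtractionConfig(),
                           ct_target=CT_TARGET_SPACING,
                           pet_target=PET_TARGET_SPACING,
                           ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """The eight feature tables keyed by image-set label, plus exclusions.

    Per patient and modality the pre- and during-treatment feature vectors
    are extracted on the resampled grids, then differenced into absolute
    and relative delta sets. Excluded patient ids (split-segment rule) are
    returned, never silently dropped.
    """
    per_set: dict[str, dict[str, FeatureVector]] = {lbl: {} for lbl in IMAGE_SET_LABELS}
    excluded = []
    for p in patients:
        prep = preprocess_patient(p, ct_target, pet_target)
        if prep is None:
            excluded.append(p.patient_id)
            continue
        vectors = extract_patient(prep, config)
        for modality in ("CT", "PET"):
            pre = vectors[(modality, "scan1")]
            during = vectors[(modality, "scan2")]
            per_set[f"{modality}-scan1"][p.patient_id] = pre
            per_set[f"{modality}-scan2"][p.patient_id] = during
            per_set[f"{modality}-abs"][p.patient_id] = delta_abs(pre, during)
            per_set[f"{modality}-rel"][p.patient_id] = delta_rel(pre, during)
    tables = {}
    for label, vectors in per_set.items():
        modality, tp = label.split("-")
        tables[label] = FeatureTable.from_vectors(vectors, modality, tp).data
    return tables, excluded


# ---------------------------------------------------------------------------
# Compact experiments reused by the analysis drivers
# ---------------------------------------------------------------------------

#: Small radiomic covariate set used by the cohort-differences model,
#: standing in for the handful of model features a prognostic model
#: would contribute.
CD_FEATURES = ("mean", "min", "sd")


def pet_scan1_feature_table(patients: list[SyntheticPatient],
                            feature_names=CD_FEATURES,
                            pet_target=PET_TARGET_SPACING) -> pd.DataFrame:
    """First-order features of the resampled pre-treatment PET scan."""
    from .features import statistical_features

    rows = {}
    for p in patients:
        img = resample(p.pet_pre, pet_target)
        mask = resample_mask_like(p.mask_pre, img)
        fv = statistical_features(img, mask)
        rows[p.patient_id] = {f"stats_{k}": fv[k] for k in feature_names}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "patient_id"
    return df


def cd_contrast_experiment(base_spec, shifted_spec, truth, n_per_cohort: int,
                           seeds, include_clinical: bool = False) -> pd.DataFrame:
    """Cohort-differences AUC for an identical-spec pair vs a shifted pair.

    For each seed, two cohorts are generated either from the same spec
    (reproducibility regime) or with acquisition shifts applied
    (transferability regime), and the pairwise CD model is fit on the
    resampled PET-scan1 features plus the two-year endpoint.
    """
    import dataclasses

    from .cohort_compare import fit_cd_model
    from .synthetic import clinical_table, generate_cohort

    rows = []
    for condition, spec_b in (("identical",
                               dataclasses.replace(base_spec, name="B")),
                              ("shifted",
                               dataclasses.replace(shifted_spec, name="B"))):
        spec_a = dataclasses.replace(base_spec, name="A",
                                     n_patients=n_per_cohort)
        spec_b = dataclasses.replace(spec_b, n_patients=n_per_cohort)
        for seed in seeds:
            pa = generate_cohort(spec_a, truth, seed=2 * seed + 1)
            pb = generate_cohort(spec_b, truth, seed=2 * seed + 2)
            pts = pa + pb
            feats = pet_scan1_feature_table(pts)
            clin = clinical_table(pts)
            res = fit_cd_model(clin, feats, "A", "B",
                               include_clinical=include_clinical)
            rows.append({"condition": condition, "seed": seed,
                         "auc": res.auc, "separation": res.separation})
    return pd.DataFrame(rows)
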