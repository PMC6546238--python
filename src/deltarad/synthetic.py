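"""Synthetic multi-cohort paired PET/CT study generator.

Emulates the heterogeneity structure of a retrospective multi-center
NSCLC delta-radiomics study: several cohorts with different native voxel
spacings, noise levels and PET intensity calibrations; ellipsoidal tumors
with Gaussian-random-field texture and controllable size and uptake;
treatment-induced shrinkage and uptake change between the two time
points; cohort-specific clinical covariate distributions; and survival
times whose log-hazard is a configurable linear function of ground-truth
tumor properties. Everything is deterministic given a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import ImageVolume, RoiMask, save_nifti

STAGES = ("II", "IIIa", "IIIb", "IV")
HISTOLOGIES = ("adenocarcinoma", "squamous-cell", "nsclc-nos")
CHEMO = ("concurrent", "sequential", "none")

#: Field of view of the phantom volume in mm (x, y, z).
DEFAULT_FOV_MM = (64.0, 64.0, 48.0)


@dataclass(frozen=True)
class CohortSpec:
    """Everything that characterizes one cohort's images and clinic."""

    name: str
    n_patients: int
    ct_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    pet_spacing: tuple[float, float, float] = (4.0, 4.0, 3.0)
    noise_sd_ct: float = 20.0          # HU
    noise_sd_pet: float = 0.15         # SUV
    intensity_offset_pet: float = 0.0  # SUV calibration shift
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)   # mm
    suvmax_range: tuple[float, float] = (6.0, 18.0)
    shrinkage_range: tuple[float, float] = (0.1, 0.6)       # volume fraction
    uptake_change_range: tuple[float, float] = (0.5, 1.0)
    stage_probs: tuple[float, float, float, float] = (0.05, 0.4, 0.45, 0.1)
    gender_prob_male: float = 0.6
    histology_probs: tuple[float, float, float] = (0.35, 0.4, 0.25)
    chemo_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    age_mean: float = 63.0
    age_sd: float = 10.0
    rt_dose_mean: float = 65.0
    rt_dose_sd: float = 6.0
    interval_prePET_RT: tuple[float, float] = (8.0, 3.0)     # mean, sd days
    interval_RT_duringPET: tuple[float, float] = (15.0, 3.0)
    texture_sd_ct: float = 40.0        # HU, tumor GRF amplitude
    texture_rel_sd_pet: float = 0.15   # relative GRF amplitude in PET
    correlation_length_mm: float = 4.0
    fov_mm: tuple[float, float, float] = DEFAULT_FOV_MM

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for probs in (self.stage_probs, self.histology_probs, self.chemo_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError("probability vectors must be nonnegative and sum to 1")
        if not 0 <= self.gender_prob_male <= 1:
            raise ValueError("gender_prob_male must be a probability")
        for rng_ in (self.tumor_radius_range, self.suvmax_range,
                     self.shrinkage_range, self.uptake_change_range):
            if rng_[0] > rng_[1]:
                raise ValueError("range lower bound exceeds upper bound")
        if not (0 <= self.shrinkage_range[0] and self.shrinkage_range[1] <= 1):
            raise ValueError("shrinkage_range must lie in [0, 1]")
        for sp in (self.ct_spacing, self.pet_spacing):
            if min(sp) <= 0:
                raise ValueError("spacings must be strictly positive")
        if self.tumor_radius_range[1] > min(self.fov_mm) / 2:
            raise ValueError("tumor radius may not exceed half the field of view")


@dataclass(frozen=True)
class SurvivalGroundTruth:
    """The generative outcome process.

    log-hazard = sum over properties of coefficient * standardized
    property; event times are exponential by default (weibull_shape = 1),
    with administrative censoring calibrated to the target rate.
    """

    baseline_hazard_scale: float = 0.35           # events per year
    log_hazard_coefficients: dict[str, float] = field(default_factory=dict)
    censoring_rate_target: float = 0.3
    weibull_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_hazard_scale <= 0:
            raise ValueError("baseline_hazard_scale must be positive")
        if not 0 <= self.censoring_rate_target < 1:
            raise ValueError("censoring_rate_target must be in [0, 1)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")


@dataclass
class PatientRecord:
    patient_id: str
    cohort: str
    age: float
    gender: str
    stage: str
    histology: str
    rt_dose: float
    chemo_timing: str
    interval_prePET_RT: float
    interval_RT_duringPET: float
    interval_between_PETs: float
    survival_time: float
    event: int
    two_year_survival: float  # 1.0 / 0.0 / nan when censored before 2 years


@dataclass
class SyntheticPatient:
    patient_id: str
    cohort: str
    ct_pre: ImageVolume | None
    ct_during: ImageVolume | None
    pet_pre: ImageVolume | None
    pet_during: ImageVolume | None
    mask_pre: RoiMask | None
    mask_during: RoiMask | None
    clinical: PatientRecord
    truth: dict[str, float]


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _grid_coords(fov, spacing):
    shape = tuple(max(2, int(round(f / s))) for f, s in zip(fov, spacing))
    axes = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)]
    return shape, np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, semiaxes):
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semiaxes))
    return q <= 1.0, q


def _random_field(rng, shape, spacing, corr_mm):
    white = rng.standard_normal(shape)
    sig = [corr_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sig, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _tumor_images(rng, spec: CohortSpec, semiaxes, center, suvmax,
                  shrinkage, uptake_change):
    """Build the four volumes and two masks for one patient.

    The during-treatment tumor is the pre-treatment ellipsoid scaled by
    (1 - shrinkage)^(1/3) in each axis (so its volume shrinks by exactly
    the drawn fraction) with uptake scaled by the drawn factor; the
    texture field is shared between time points, noise is fresh.
    """
    scale = (1.0 - shrinkage) ** (1.0 / 3.0)
    out = {}
    masks = {}
    for modality in ("CT", "PET"):
        spacing = spec.ct_spacing if modality == "CT" else spec.pet_spacing
        shape, coords = _grid_coords(spec.fov_mm, spacing)
        texture = _random_field(rng, shape, spacing, spec.correlation_length_mm)
        for tp, ax_scale, uptake in (("pre", 1.0, 1.0),
                                     ("during", scale, uptake_change)):
            inside, q = _ellipsoid(coords, center,
                                   [a * ax_scale for a in semiaxes])
            if modality == "CT":
                img = np.full(shape, -700.0)
                img[inside] = 20.0 + spec.texture_sd_ct * texture[inside]
                img += rng.normal(0.0, spec.noise_sd_ct, shape)
                vol = ImageVolume(img, spacing, modality="CT")
            else:
                img = np.full(shape, 0.8)
                profile = np.clip(1.0 - 0.5 * q, 0.0, 1.0)
                hot = suvmax * uptake * profile
                tex = 1.0 + spec.texture_rel_sd_pet * texture
                img[inside] = np.maximum(img[inside],
                                         (hot * tex)[inside])
                img += spec.intensity_offset_pet
                img += rng.normal(0.0, spec.noise_sd_pet, shape)
                np.clip(img, 0.0, None, out=img)
                vol = ImageVolume(img, spacing, modality="PET-SUV")
            out[f"{'ct' if modality == 'CT' else 'pet'}_{tp}"] = vol
            if modality == "CT":
                # masks live on the finer CT grid; the pipeline resamples
                # them onto each modality's common grid
                masks[tp] = RoiMask(inside, spacing)
    out["mask_pre"], out["mask_during"] = masks["pre"], masks["during"]
    return out


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def draw_survival(log_hazard: np.ndarray, truth: SurvivalGroundTruth,
                  rng: np.random.Generator):
    """Draw (time, event) under the proportional-hazards generative model.

    Event times are Weibull with the configured shape (exponential for
    shape 1) and rate scaled by exp(log_hazard). Administrative censoring
    at the empirical (1 - target) quantile of the drawn event times
    calibrates the observed censoring fraction to the target.
    """
    n = len(log_hazard)
    u = rng.uniform(size=n)
    lam = truth.baseline_hazard_scale * np.exp(log_hazard)
    t = (-np.log(u) / lam) ** (1.0 / truth.weibull_shape)
    if truth.censoring_rate_target > 0:
        c = np.quantile(t, 1.0 - truth.censoring_rate_target)
        event = (t <= c).astype(int)
        time = np.minimum(t, c)
    else:
        event = np.ones(n, dtype=int)
        time = t
    return np.maximum(time, 1e-6), event


def two_year_survival(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Binary two-year endpoint; NaN when censored before two years."""
    out = np.where(time > 2.0, 1.0, np.where(event == 1, 0.0, np.nan))
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(spec: CohortSpec, truth: SurvivalGroundTruth,
                    seed: int, with_images: bool = True) -> list[SyntheticPatient]:
    """Generate one cohort of paired-time-point patients with ground truth.

    ``with_images=False`` skips volume synthesis (image fields are None)
    but draws identical clinical, truth and survival values for the same
    seed — a fast path for outcome-model simulations.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    radius = rng.uniform(*spec.tumor_radius_range, size=n)
    axis_jit = rng.uniform(0.8, 1.2, size=(n, 3))
    suvmax = rng.uniform(*spec.suvmax_range, size=n)
    shrinkage = rng.uniform(*spec.shrinkage_range, size=n)
    uptake_change = rng.uniform(*spec.uptake_change_range, size=n)
    jitter = rng.uniform(-3.0, 3.0, size=(n, 3))

    semiaxes = radius[:, None] * axis_jit
    volume = 4.0 / 3.0 * np.pi * semiaxes.prod(axis=1)
    props = {
        "tumor_volume": volume,
        "log_volume": np.log(volume),
        "suvmax": suvmax,
        "shrinkage": shrinkage,
        "uptake_change": uptake_change,
    }
    log_hazard = np.zeros(n)
    for name, coef in truth.log_hazard_coefficients.items():
        if name not in props:
            raise KeyError(f"unknown ground-truth property {name!r}")
        log_hazard += coef * _standardize(props[name])
    time, event = draw_survival(log_hazard, truth, rng)
    ty = two_year_survival(time, event)

    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    gender = np.where(rng.uniform(size=n) < spec.gender_prob_male,
                      "male", "female")
    stage = rng.choice(STAGES, size=n, p=spec.stage_probs)
    histology = rng.choice(HISTOLOGIES, size=n, p=spec.histology_probs)
    chemo = rng.choice(CHEMO, size=n, p=spec.chemo_probs)
    rt_dose = rng.normal(spec.rt_dose_mean, spec.rt_dose_sd, size=n)
    iv1 = np.maximum(rng.normal(*spec.interval_prePET_RT, size=n), 1.0)
    iv2 = np.maximum(rng.normal(*spec.interval_RT_duringPET, size=n), 1.0)

    patients = []
    for i in range(n):
        pid = f"{spec.name}-{i:03d}"
        if with_images:
            vols = _tumor_images(rng, spec, semiaxes[i], jitter[i], suvmax[i],
                                 shrinkage[i], uptake_change[i])
        else:
            vols = dict.fromkeys(("ct_pre", "ct_during", "pet_pre",
                                  "pet_during", "mask_pre", "mask_during"))
        record = PatientRecord(
            patient_id=pid, cohort=spec.name,
            age=float(age[i]), gender=str(gender[i]), stage=str(stage[i]),
            histology=str(histology[i]), rt_dose=float(rt_dose[i]),
            chemo_timing=str(chemo[i]),
            interval_prePET_RT=float(iv1[i]),
            interval_RT_duringPET=float(iv2[i]),
            interval_between_PETs=float(iv1[i] + iv2[i]),
            survival_time=float(time[i]), event=int(event[i]),
            two_year_survival=float(ty[i]),
        )
        patients.append(SyntheticPatient(
            patient_id=pid, cohort=spec.name,
            ct_pre=vols["ct_pre"], ct_during=vols["ct_during"],
            pet_pre=vols["pet_pre"], pet_during=vols["pet_during"],
            mask_pre=vols["mask_pre"], mask_during=vols["mask_during"],
            clinical=record,
            truth={k: float(v[i]) for k, v in props.items()},
        ))
    return patients


def clinical_table(patients: list[SyntheticPatient]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(p.clinical) for p in patients])
    return df.set_index("patient_id").sort_index()


def truth_table(patients: list[SyntheticPatient]) -> pd.DataFrame:
    rows = {p.patient_id: p.truth for p in patients}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "patient_id"
    return df


def generate_study(specs: list[CohortSpec], truth: SurvivalGroundTruth,
                   seed: int, out_dir: str | Path | None = None):
    """Generate a multi-cohort study; optionally write it to disk.

    Per-cohort seeds are derived deterministically from the study seed, so
    the bundle is byte-identical across reruns. When ``out_dir`` is given,
    each patient's four volumes and two masks are written as NIfTI, the
    clinical table as CSV, and a manifest (seeds, spec digest) as JSON.
    """
    if len(specs) < 2:
        raise ValueError("a study needs at least two cohorts")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cohort names")
    ss = np.random.SeedSequence(seed)
    cohort_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(specs))]
    patients: list[SyntheticPatient] = []
    for spec, cseed in zip(specs, cohort_seeds):
        patients.extend(generate_cohort(spec, truth, cseed))
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids across cohorts")
    clin = clinical_table(patients)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        for p in patients:
            for tag in ("ct_pre", "ct_during", "pet_pre", "pet_during",
                        "mask_pre", "mask_during"):
                save_nifti(getattr(p, tag),
                           out_dir / "images" / f"{p.patient_id}_{tag}.nii")
        clin.to_csv(out_dir / "clinical.csv")
        digest = hashlib.sha256(
            json.dumps([asdict(s) for s in specs], sort_keys=True).encode()
        ).hexdigest()
        manifest = {"seed": seed, "cohort_seeds": cohort_seeds,
                    "cohorts": names, "spec_sha256": digest}
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return patients, clin


def default_study_specs(n_scale: float = 1.0) -> list[CohortSpec]:
    """Four cohorts emulating the imaging/clinical heterogeneity of a
    multi-center NSCLC study (different scanners, spacings, calibrations,
    stage and gender mixes). ``n_scale`` scales all cohort sizes."""
    def n(base):
        return max(2, int(round(base * n_scale)))

    return [
        CohortSpec(name="cohort1", n_patients=n(50),
                   ct_spacing=(0.98, 0.98, 3.0), pet_spacing=(4.07, 4.07, 3.0),
                   noise_sd_ct=20.0, noise_sd_pet=0.15, intensity_offset_pet=0.0,
                   stage_probs=(0.0, 0.34, 0.54, 0.12), gender_prob_male=0.50,
                   histology_probs=(0.36, 0.28, 0.36), chemo_probs=(1.0, 0.0, 0.0),
                   age_mean=62.0, age_sd=11.0, rt_dose_mean=64.0, rt_dose_sd=6.0,
                   interval_prePET_RT=(7.0, 2.0), interval_RT_duringPET=(15.0, 2.0)),
        CohortSpec(name="cohort2", n_patients=n(31),
                   ct_spacing=(0.98, 0.98, 3.0), pet_spacing=(4.07, 4.07, 3.0),
                   noise_sd_ct=20.0, noise_sd_pet=0.15, intensity_offset_pet=0.4,
                   stage_probs=(2 / 31, 14 / 31, 15 / 31, 0.0), gender_prob_male=0.71,
                   histology_probs=(6 / 31, 9 / 31, 16 / 31),
                   chemo_probs=(13 / 31, 17 / 31, 1 / 31),
                   age_mean=65.0, age_sd=9.0, rt_dose_mean=61.0, rt_dose_sd=7.0,
                   interval_prePET_RT=(8.0, 2.0), interval_RT_duringPET=(9.0, 3.0)),
        CohortSpec(name="cohort3", n_patients=n(27),
                   ct_spacing=(1.2, 1.2, 5.0), pet_spacing=(4.0, 4.0, 4.0),
                   noise_sd_ct=30.0, noise_sd_pet=0.25, intensity_offset_pet=-0.3,
                   stage_probs=(4 / 27, 16 / 27, 7 / 27, 0.0), gender_prob_male=0.93,
                   histology_probs=(11 / 27, 14 / 27, 2 / 27),
                   chemo_probs=(1.0, 0.0, 0.0),
                   age_mean=61.0, age_sd=8.0, rt_dose_mean=68.0, rt_dose_sd=2.0,
                   interval_prePET_RT=(38.0, 21.0), interval_RT_duringPET=(21.0, 4.0)),
        CohortSpec(name="cohort4", n_patients=n(30),
                   ct_spacing=(1.2, 1.2, 2.0), pet_spacing=(2.0, 2.0, 2.0),
                   noise_sd_ct=25.0, noise_sd_pet=0.10, intensity_offset_pet=0.2,
                   stage_probs=(1 / 30, 16 / 30, 13 / 30, 0.0), gender_prob_male=0.63,
                   histology_probs=(9 / 30, 18 / 30, 3 / 30),
                   chemo_probs=(1.0, 0.0, 0.0),
                   age_mean=65.0, age_sd=9.0, rt_dose_mean=66.0, rt_dose_sd=8.0,
                   interval_prePET_RT=(17.0, 7.0), interval_RT_duringPET=(16.0, 3.0)),
    ]
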