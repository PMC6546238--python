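"""Non-texture radiomic feature groups.

Covers morphology (shape), local intensity peaks, first-order statistics,
discretized intensity-histogram features, the PET intensity-volume
histogram (MTV/TLG at 10-90% of SUVmax), and box-counting fractal
features of the thresholded intensity surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull
from skimage import measure

from .discretize import DiscretizationConfig, discretize
from .featurevector import FeatureVector
from .images import ImageVolume, RoiMask

#: Radius (mm) of a 1 cm^3 sphere, used for SUVpeak-style local peaks.
PEAK_SPHERE_RADIUS_MM = (3000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def shape_features(mask: RoiMask) -> FeatureVector:
    """Morphological features of a single-segment ROI.

    Volume is voxel count times voxel volume (mm^3); surface area comes
    from a marching-cubes mesh of the binarized ROI (mm^2); the maximum 3D
    diameter is the largest distance between ROI voxel centers.
    """
    if mask.n_components != 1:
        raise ValueError("shape features require a single-segment mask")
    fv = FeatureVector()
    volume = mask.volume_mm3
    fv.set("volume", volume)

    padded = np.pad(mask.values.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=mask.spacing)
    area = measure.mesh_surface_area(verts, faces)
    fv.set("surface-area", area)
    fv.set("surface-to-volume-ratio", area / volume)
    fv.set("sphericity", np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    fv.set("compactness", volume / (np.sqrt(np.pi) * area ** 1.5))

    coords = np.argwhere(mask.values) * np.asarray(mask.spacing)
    if len(coords) >= 5:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    fv.set("max-3d-diameter", float(np.sqrt(d2.max())))
    return fv


# ---------------------------------------------------------------------------
# Local intensity
# ---------------------------------------------------------------------------

def _sphere_mean_map(img: ImageVolume) -> np.ndarray:
    """Mean intensity in a 1 cm^3 sphere centered at each voxel.

    The sphere membership test uses voxel centers; near the image edge the
    mean runs over in-image sphere voxels only.
    """
    sp = np.asarray(img.spacing)
    half = np.floor(PEAK_SPHERE_RADIUS_MM / sp).astype(int)
    offs = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    offs = np.stack([o.ravel() for o in offs], axis=1)
    inside = (offs * sp) ** 2
    kernel = np.zeros(tuple(2 * h + 1 for h in half))
    sel = inside.sum(axis=1) <= PEAK_SPHERE_RADIUS_MM ** 2
    kernel[tuple((offs[sel] + half).T)] = 1.0
    num = ndimage.convolve(img.values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones(img.shape), kernel, mode="constant", cval=0.0)
    return num / den


def local_intensity_features(img: ImageVolume, mask: RoiMask) -> FeatureVector:
    """Global intensity peak (SUVpeak on PET) and local intensity peak."""
    fv = FeatureVector()
    means = _sphere_mean_map(img)
    roi = mask.values
    fv.set("global-peak", float(means[roi].max()))
    vmax = img.values[roi].max()
    at_max = roi & (img.values == vmax)
    fv.set("local-peak", float(means[at_max].max()))
    return fv


def suv_peak(img: ImageVolume, mask: RoiMask) -> float:
    """SUVpeak: maximum 1 cm^3 sphere-mean over ROI voxels."""
    return local_intensity_features(img, mask)["global-peak"]


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def statistical_features(img: ImageVolume, mask: RoiMask) -> FeatureVector:
    x = img.values[mask.values]
    fv = FeatureVector()
    sd = float(x.std())  # population sd
    fv.set("mean", x.mean())
    fv.set("sd", sd)
    fv.set("variance", x.var())
    # undefined-as-zero convention for the standardized moments of a
    # constant ROI
    fv.set("skewness", float(stats.skew(x)) if sd > 0 else 0.0)
    fv.set("kurtosis", float(stats.kurtosis(x)) if sd > 0 else 0.0)
    fv.set("median", np.median(x))
    fv.set("min", x.min())
    fv.set("max", x.max())
    fv.set("p10", np.percentile(x, 10))
    fv.set("p90", np.percentile(x, 90))
    fv.set("iqr", np.percentile(x, 75) - np.percentile(x, 25))
    fv.set("range", x.max() - x.min())
    fv.set("energy", (x ** 2).sum())
    fv.set("rms", np.sqrt((x ** 2).mean()))
    fv.set("mad", np.abs(x - x.mean()).mean())
    return fv


# ---------------------------------------------------------------------------
# Intensity histogram (discretized)
# ---------------------------------------------------------------------------

def intensity_histogram_features(img: ImageVolume, mask: RoiMask,
                                 disc: DiscretizationConfig) -> FeatureVector:
    lv, n = discretize(img.values[mask.values], disc)
    counts = np.bincount(lv, minlength=n + 1)[1:].astype(np.float64)
    p = counts / counts.sum()
    fv = FeatureVector()
    pos = p[p > 0]
    fv.set("entropy", float(-(pos * np.log2(pos)).sum()))
    fv.set("uniformity", float((p ** 2).sum()))
    fv.set("mode", float(np.argmax(counts) + 1))  # ties -> lowest level
    levels = np.arange(1, n + 1, dtype=np.float64)
    mu = float((p * levels).sum())
    var = float((p * (levels - mu) ** 2).sum())
    fv.set("mean", mu)
    fv.set("variance", var)
    if var > 0:
        fv.set("skewness", float((p * (levels - mu) ** 3).sum()) / var ** 1.5)
        fv.set("kurtosis", float((p * (levels - mu) ** 4).sum()) / var ** 2 - 3.0)
    else:
        fv.set("skewness", 0.0)
        fv.set("kurtosis", 0.0)
    return fv


# ---------------------------------------------------------------------------
# Intensity-volume histogram (PET only)
# ---------------------------------------------------------------------------

IVH_THRESHOLD_PERCENTS = tuple(range(10, 100, 10))


@dataclass
class IvhCurve:
    """MTV/TLG as a function of the SUVmax-fraction threshold.

    thresholds are percentages (10..90); mtv in mm^3; tlg in SUV*mm^3.
    """

    thresholds: tuple[int, ...]
    mtv: np.ndarray
    tlg: np.ndarray


def ivh_features(img: ImageVolume, mask: RoiMask) -> tuple[IvhCurve, FeatureVector]:
    """MTV_x and TLG_x for x in 10..90% of SUVmax (inclusive threshold).

    MTV_x is the volume of ROI voxels with SUV >= x% of SUVmax; TLG_x is
    MTV_x times the mean SUV over those voxels.
    """
    if img.modality != "PET-SUV":
        raise ValueError("IVH features are defined on PET-SUV images only")
    x = img.values[mask.values]
    suvmax = float(x.max())
    if suvmax <= 0:
        raise ValueError("SUVmax must be positive for IVH features")
    vv = mask.voxel_volume
    mtv = np.empty(len(IVH_THRESHOLD_PERCENTS))
    tlg = np.empty(len(IVH_THRESHOLD_PERCENTS))
    for idx, pct in enumerate(IVH_THRESHOLD_PERCENTS):
        sel = x >= suvmax * pct / 100.0
        mtv[idx] = sel.sum() * vv
        tlg[idx] = mtv[idx] * (x[sel].mean() if sel.any() else 0.0)
    curve = IvhCurve(IVH_THRESHOLD_PERCENTS, mtv, tlg)
    fv = FeatureVector()
    for idx, pct in enumerate(IVH_THRESHOLD_PERCENTS):
        fv.set(f"MTV-{pct}", mtv[idx])
        fv.set(f"TLG-{pct}", tlg[idx])
    return curve, fv


# ---------------------------------------------------------------------------
# Fractal features
# ---------------------------------------------------------------------------

def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting dimension of a binary 3D set.

    Box sizes are powers of 2 up to half the bounding-box extent; the
    dimension is the least-squares slope of log(count) against log(1/size).
    An empty set or a single usable box size yields 0.
    """
    if not binary.any():
        return 0.0
    coords = np.argwhere(binary)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    sub = binary[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    max_extent = max(sub.shape)
    sizes = []
    s = 1
    while s <= max(1, max_extent // 2):
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0
    counts = []
    for s in sizes:
        pads = [(0, (-d) % s) for d in sub.shape]
        blocks = np.pad(sub, pads).reshape(
            (sub.shape[0] + pads[0][1]) // s, s,
            (sub.shape[1] + pads[1][1]) // s, s,
            (sub.shape[2] + pads[2][1]) // s, s)
        counts.append(blocks.any(axis=(1, 3, 5)).sum())
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(np.asarray(counts, dtype=float)), 1)[0]
    return float(slope)


def _lacunarity(binary: np.ndarray) -> float:
    """Mean over box sizes of var(box mass)/mean(box mass)^2 + 1."""
    coords = np.argwhere(binary)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    sub = binary[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    vals = []
    s = 2
    while s <= max(2, max(sub.shape) // 2):
        pads = [(0, (-d) % s) for d in sub.shape]
        blocks = np.pad(sub, pads).reshape(
            (sub.shape[0] + pads[0][1]) // s, s,
            (sub.shape[1] + pads[1][1]) // s, s,
            (sub.shape[2] + pads[2][1]) // s, s)
        mass = blocks.sum(axis=(1, 3, 5)).ravel()
        if mass.mean() > 0:
            vals.append(mass.var() / mass.mean() ** 2 + 1.0)
        s *= 2
    return float(np.mean(vals)) if vals else 1.0


FRACTAL_THRESHOLD_FRACTIONS = tuple(f / 10.0 for f in range(1, 10))


def fractal_features(img: ImageVolume, mask: RoiMask) -> FeatureVector:
    """Box-counting dimension of the thresholded intensity surface.

    The ROI intensity range is swept at fractions 0.1..0.9; the per-
    threshold dimensions are summarized by their mean and sd, plus the
    gliding-box lacunarity of the half-range threshold set.
    """
    roi = mask.values
    x = img.values[roi]
    lo, hi = float(x.min()), float(x.max())
    dims = []
    for f in FRACTAL_THRESHOLD_FRACTIONS:
        t = lo + f * (hi - lo)
        dims.append(box_counting_dimension(roi & (img.values >= t)))
    fv = FeatureVector()
    fv.set("dimension-mean", float(np.mean(dims)))
    fv.set("dimension-sd", float(np.std(dims)))
    mid = lo + 0.5 * (hi - lo)
    fv.set("lacunarity", _lacunarity(roi & (img.values >= mid)))
    return fv
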