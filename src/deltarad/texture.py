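"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, NGTDM, GLDZM, NGLDM).

All matrices are built in 3D on the discretized ROI. Pairwise/run families
use the 13 unique direction vectors at Chebyshev distance 1, either merged
into a single matrix (default) or computed per direction and averaged at
the feature level. Zone families use 26-connectivity; neighborhood families
use the full 26-neighborhood. GLDZM distances are Chebyshev distances to
the ROI border, with surface voxels at distance 1 and the image edge
counting as border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizationConfig, discretize
from .featurevector import FeatureVector
from .images import STRUCT_26, ImageVolume, RoiMask

TEXTURE_KINDS = ("GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDZM", "NGLDM")

#: The 13 unique 3D direction vectors at Chebyshev distance 1 (one per
#: antipodal pair).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: 26-neighborhood kernel (center excluded).
_KERNEL_26 = np.ones((3, 3, 3))
_KERNEL_26[1, 1, 1] = 0.0


@dataclass
class TextureMatrix:
    """A gray-level texture matrix plus the bookkeeping features need.

    matrix rows index gray level 1..n_levels; columns index the family's
    second quantity (co-occurring level, run length, zone size, zone
    distance, or dependence count + 1). For NGTDM, ``ngtdm_s`` holds the
    per-level summed absolute tone difference.
    """

    kind: str
    matrix: np.ndarray
    aggregation: str
    n_levels: int
    n_voxels: int
    ngtdm_s: np.ndarray | None = None
    submatrices: list[np.ndarray] | None = None  # per-direction, if requested


def _level_grid(img: ImageVolume, mask: RoiMask,
                disc: DiscretizationConfig) -> tuple[np.ndarray, int]:
    """Discretized levels on the full grid: 0 outside the ROI, 1..n inside."""
    roi_values = img.values[mask.values]
    if roi_values.size == 0:
        raise ValueError("empty ROI")
    lv, n_levels = discretize(roi_values, disc)
    grid = np.zeros(img.shape, dtype=np.int64)
    grid[mask.values] = lv
    return grid, n_levels


def _shift(grid: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """grid sampled at v + d, with 0 outside the array."""
    out = np.zeros_like(grid)
    src = tuple(slice(max(dd, 0), grid.shape[a] + min(dd, 0))
                for a, dd in enumerate(d))
    dst = tuple(slice(max(-dd, 0), grid.shape[a] + min(-dd, 0))
                for a, dd in enumerate(d))
    out[dst] = grid[src]
    return out


def _glcm_one(grid: np.ndarray, n: int, d) -> np.ndarray:
    nb = _shift(grid, d)
    ok = (grid > 0) & (nb > 0)
    m = np.zeros((n, n))
    if ok.any():
        np.add.at(m, (grid[ok] - 1, nb[ok] - 1), 1.0)
    return m + m.T  # symmetric convention


def _glrlm_one(grid: np.ndarray, n: int, d) -> np.ndarray:
    prev = _shift(grid, tuple(-x for x in d))
    starts = (grid > 0) & (prev != grid)
    coords = np.argwhere(starts)
    levels = grid[starts]
    max_len = int(np.ceil(np.linalg.norm(grid.shape) / max(np.abs(d)))) + 2
    m = np.zeros((n, max_len))
    cur = coords.copy()
    alive = np.arange(len(coords))
    length = np.ones(len(coords), dtype=np.int64)
    dv = np.asarray(d)
    while alive.size:
        cur = cur + dv
        inb = np.all((cur >= 0) & (cur < np.asarray(grid.shape)), axis=1)
        same = np.zeros(len(alive), dtype=bool)
        if inb.any():
            same[inb] = grid[tuple(cur[inb].T)] == levels[alive][inb]
        length[alive[same]] += 1
        alive = alive[same]
        cur = cur[same]
    np.add.at(m, (levels - 1, length - 1), 1.0)
    # trim trailing all-zero run-length columns
    last = int(np.max(np.nonzero(m.sum(axis=0))[0])) if m.any() else 0
    return m[:, : last + 1]


def _zone_sizes(grid: np.ndarray, n: int):
    """26-connected zones per gray level: yields (level, sizes, labeled, n_zones)."""
    for lvl in range(1, n + 1):
        binary = grid == lvl
        if not binary.any():
            continue
        labeled, k = ndimage.label(binary, structure=STRUCT_26)
        sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, k + 1))
        yield lvl, sizes.astype(np.int64), labeled, k


def _glszm(grid: np.ndarray, n: int) -> np.ndarray:
    entries = []
    for lvl, sizes, _, _ in _zone_sizes(grid, n):
        for s in sizes:
            entries.append((lvl, s))
    max_size = max(s for _, s in entries)
    m = np.zeros((n, max_size))
    for lvl, s in entries:
        m[lvl - 1, s - 1] += 1.0
    return m


def _gldzm(grid: np.ndarray, roi: np.ndarray, n: int) -> np.ndarray:
    # Chebyshev distance to border; image edge counts as border, surface
    # voxels sit at distance 1.
    padded = np.pad(roi, 1)
    dmap = ndimage.distance_transform_cdt(padded, metric="chessboard")
    dmap = dmap[1:-1, 1:-1, 1:-1]
    entries = []
    for lvl, _, labeled, k in _zone_sizes(grid, n):
        mins = ndimage.minimum(dmap, labeled, index=np.arange(1, k + 1))
        for dmin in np.atleast_1d(mins):
            entries.append((lvl, int(dmin)))
    max_d = max(d for _, d in entries)
    m = np.zeros((n, max_d))
    for lvl, d in entries:
        m[lvl - 1, d - 1] += 1.0
    return m


def _neighbor_stats(grid: np.ndarray, roi: np.ndarray):
    """Per-voxel sum and count of in-ROI 26-neighbors' gray levels."""
    nb_sum = ndimage.convolve(grid.astype(np.float64), _KERNEL_26,
                              mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(roi.astype(np.float64), _KERNEL_26,
                              mode="constant", cval=0.0)
    return nb_sum, nb_cnt


def _ngtdm(grid: np.ndarray, roi: np.ndarray, n: int):
    nb_sum, nb_cnt = _neighbor_stats(grid, roi)
    valid = roi & (nb_cnt > 0)
    diffs = np.zeros(grid.shape)
    diffs[valid] = np.abs(grid[valid] - nb_sum[valid] / nb_cnt[valid])
    s = np.zeros(n)
    counts = np.zeros(n)
    for lvl in range(1, n + 1):
        sel = valid & (grid == lvl)
        s[lvl - 1] = diffs[sel].sum()
        counts[lvl - 1] = sel.sum()
    return counts.reshape(-1, 1), s


def _ngldm(grid: np.ndarray, roi: np.ndarray, n: int,
           alpha: int = 0) -> np.ndarray:
    max_k = 26
    m = np.zeros((n, max_k + 1))
    for lvl in range(1, n + 1):
        center = grid == lvl
        if not center.any():
            continue
        dependent = (np.abs(grid - lvl) <= alpha) & roi
        k = ndimage.convolve(dependent.astype(np.float64), _KERNEL_26,
                             mode="constant", cval=0.0)
        kk = np.rint(k[center]).astype(np.int64)
        np.add.at(m, (lvl - 1, kk), 1.0)
    last = int(np.max(np.nonzero(m.sum(axis=0))[0]))
    return m[:, : last + 1]


def build_texture_matrix(img: ImageVolume, mask: RoiMask,
                         disc: DiscretizationConfig, kind: str,
                         aggregation: str = "merged-3D-directions",
                         ngldm_alpha: int = 0) -> TextureMatrix:
    """Build one texture matrix family on the discretized ROI."""
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"unknown texture matrix kind {kind!r}")
    if aggregation not in ("merged-3D-directions", "per-direction-averaged"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    grid, n = _level_grid(img, mask, disc)
    roi = mask.values
    n_voxels = int(roi.sum())
    ngtdm_s = None
    submatrices = None
    if kind == "GLCM":
        mats = [_glcm_one(grid, n, d) for d in DIRECTIONS_13]
        if aggregation == "merged-3D-directions":
            matrix = np.sum(mats, axis=0)
        else:
            matrix = np.sum(mats, axis=0)
            submatrices = mats
    elif kind == "GLRLM":
        mats = [_glrlm_one(grid, n, d) for d in DIRECTIONS_13]
        width = max(m.shape[1] for m in mats)
        mats = [np.pad(m, ((0, 0), (0, width - m.shape[1]))) for m in mats]
        matrix = np.sum(mats, axis=0)
        if aggregation == "per-direction-averaged":
            submatrices = mats
    elif kind == "GLSZM":
        matrix = _glszm(grid, n)
    elif kind == "GLDZM":
        matrix = _gldzm(grid, roi, n)
    elif kind == "NGTDM":
        matrix, ngtdm_s = _ngtdm(grid, roi, n)
    else:  # NGLDM
        matrix = _ngldm(grid, roi, n, alpha=ngldm_alpha)
    return TextureMatrix(kind=kind, matrix=matrix, aggregation=aggregation,
                         n_levels=n, n_voxels=n_voxels, ngtdm_s=ngtdm_s,
                         submatrices=submatrices)


# ---------------------------------------------------------------------------
# Feature statistics derived from the matrices
# ---------------------------------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    pos = p[p > 0]
    return float(-(pos * np.log2(pos)).sum())


def _glcm_features(counts: np.ndarray) -> FeatureVector:
    fv = FeatureVector()
    n = counts.shape[0]
    total = counts.sum()
    p = counts / total
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    px = p.sum(axis=1)
    mu = float((np.arange(1, n + 1) * px).sum())
    sigma2 = float(((np.arange(1, n + 1) - mu) ** 2 * px).sum())
    fv.set("joint-maximum", p.max())
    fv.set("joint-energy", (p ** 2).sum())
    fv.set("joint-entropy", _entropy(p))
    fv.set("contrast", (p * (i - j) ** 2).sum())
    fv.set("dissimilarity", (p * np.abs(i - j)).sum())
    fv.set("inverse-difference", (p / (1.0 + np.abs(i - j))).sum())
    fv.set("inverse-difference-moment", (p / (1.0 + (i - j) ** 2)).sum())
    off = i != j
    iv = (p[off] / (i[off] - j[off]) ** 2).sum() if off.any() else 0.0
    fv.set("inverse-variance", iv)
    if sigma2 > 0:
        corr = ((p * (i - mu) * (j - mu)).sum()) / sigma2
        fv.set("correlation", corr)
    else:
        fv.set("correlation", float("nan"), missing_reason="constant-roi")
    fv.set("autocorrelation", (p * i * j).sum())
    fv.set("sum-average", (p * (i + j)).sum())
    fv.set("cluster-tendency", (p * (i + j - 2 * mu) ** 2).sum())
    fv.set("cluster-shade", (p * (i + j - 2 * mu) ** 3).sum())
    fv.set("cluster-prominence", (p * (i + j - 2 * mu) ** 4).sum())
    return fv


def _run_zone_features(counts: np.ndarray, n_voxels: int,
                       axis_name: str) -> FeatureVector:
    """Shared statistics for GLRLM/GLSZM/GLDZM-shaped matrices.

    axis_name in {run, zone, distance} controls naming only; column index j
    means run length, zone size or zone distance respectively.
    """
    fv = FeatureVector()
    ni, nj = counts.shape
    ns = counts.sum()
    p = counts / ns
    i, j = np.meshgrid(np.arange(1, ni + 1), np.arange(1, nj + 1), indexing="ij")
    short = {"run": "short-run", "zone": "small-zone", "distance": "small-distance"}[axis_name]
    long_ = {"run": "long-run", "zone": "large-zone", "distance": "large-distance"}[axis_name]
    fv.set(f"{short}-emphasis", (p / j ** 2).sum())
    fv.set(f"{long_}-emphasis", (p * j ** 2).sum())
    fv.set("low-gray-level-emphasis", (p / i ** 2).sum())
    fv.set("high-gray-level-emphasis", (p * i ** 2).sum())
    fv.set(f"{short}-low-gray-level-emphasis", (p / (i ** 2 * j ** 2)).sum())
    fv.set(f"{short}-high-gray-level-emphasis", (p * i ** 2 / j ** 2).sum())
    fv.set(f"{long_}-low-gray-level-emphasis", (p * j ** 2 / i ** 2).sum())
    fv.set(f"{long_}-high-gray-level-emphasis", (p * i ** 2 * j ** 2).sum())
    fv.set("gray-level-nonuniformity", (counts.sum(axis=1) ** 2).sum() / ns)
    fv.set(f"{axis_name}-nonuniformity", (counts.sum(axis=0) ** 2).sum() / ns)
    fv.set(f"{axis_name}-percentage", ns / n_voxels)
    fv.set(f"{axis_name}-entropy", _entropy(p))
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    fv.set("gray-level-variance", (p * (i - mu_i) ** 2).sum())
    fv.set(f"{axis_name}-variance", (p * (j - mu_j) ** 2).sum())
    if axis_name in ("zone", "distance"):
        # inverse-variance convention: inverse-squared size/distance
        # weighting, i.e. numerically the small-emphasis statistic
        fv.set("inverse-variance", (p / j ** 2).sum())
    return fv


def _ngtdm_features(counts: np.ndarray, s: np.ndarray,
                    n_voxels: int) -> FeatureVector:
    fv = FeatureVector()
    n_valid = counts.sum()
    pi = counts.ravel() / n_valid
    levels = np.arange(1, len(pi) + 1, dtype=np.float64)
    present = pi > 0
    ngp = int(present.sum())
    denom_coarse = float((pi * s).sum())
    if denom_coarse > 0:
        fv.set("coarseness", 1.0 / denom_coarse)
    else:
        fv.set("coarseness", float("nan"), missing_reason="flat-neighborhoods")
    if ngp > 1:
        ii, jj = np.meshgrid(levels[present], levels[present], indexing="ij")
        ppi, ppj = np.meshgrid(pi[present], pi[present], indexing="ij")
        ssi, ssj = np.meshgrid(s[present], s[present], indexing="ij")
        fv.set("contrast",
               float((ppi * ppj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))
                     * s.sum() / n_valid))
        denom_busy = float(np.abs(levels[present, None] * pi[present, None]
                                  - levels[None, present] * pi[None, present]).sum())
        if denom_busy > 0:
            fv.set("busyness", denom_coarse / denom_busy)
        else:
            fv.set("busyness", float("nan"), missing_reason="degenerate")
        fv.set("complexity",
               float((np.abs(ii - jj) * (ppi * ssi + ppj * ssj)
                      / (ppi + ppj)).sum() / n_valid))
        fv.set("strength", float(((ppi + ppj) * (ii - jj) ** 2).sum()
                                 / denom_coarse) if denom_coarse > 0 else 0.0)
    else:
        for name in ("contrast", "busyness", "complexity", "strength"):
            fv.set(name, float("nan"), missing_reason="single-gray-level")
    return fv


def _ngldm_features(counts: np.ndarray, n_voxels: int) -> FeatureVector:
    """Dependence-count features; column c holds dependence count c-1, and
    emphases weight by j = count + 1 so zero-dependence voxels stay finite."""
    fv = FeatureVector()
    ni, nj = counts.shape
    ns = counts.sum()
    p = counts / ns
    i, j = np.meshgrid(np.arange(1, ni + 1), np.arange(1, nj + 1), indexing="ij")
    fv.set("low-dependence-emphasis", (p / j ** 2).sum())
    fv.set("high-dependence-emphasis", (p * j ** 2).sum())
    fv.set("low-gray-level-emphasis", (p / i ** 2).sum())
    fv.set("high-gray-level-emphasis", (p * i ** 2).sum())
    fv.set("low-dependence-low-gray-level-emphasis", (p / (i ** 2 * j ** 2)).sum())
    fv.set("low-dependence-high-gray-level-emphasis", (p * i ** 2 / j ** 2).sum())
    fv.set("high-dependence-low-gray-level-emphasis", (p * j ** 2 / i ** 2).sum())
    fv.set("high-dependence-high-gray-level-emphasis", (p * i ** 2 * j ** 2).sum())
    fv.set("gray-level-nonuniformity", (counts.sum(axis=1) ** 2).sum() / ns)
    fv.set("dependence-count-nonuniformity", (counts.sum(axis=0) ** 2).sum() / ns)
    fv.set("dependence-count-entropy", _entropy(p))
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    fv.set("gray-level-variance", (p * (i - mu_i) ** 2).sum())
    fv.set("dependence-count-variance", (p * (j - mu_j) ** 2).sum())
    return fv


def texture_features(tm: TextureMatrix) -> FeatureVector:
    """Derive the named statistics for one texture matrix.

    Matrices are normalized to probabilities first, so features are
    invariant to matrix scaling. Under per-direction aggregation the
    statistics are computed per direction and averaged.
    """
    if tm.kind == "NGTDM":
        return _ngtdm_features(tm.matrix, tm.ngtdm_s, tm.n_voxels)
    if tm.kind == "NGLDM":
        return _ngldm_features(tm.matrix, tm.n_voxels)

    def one(mat: np.ndarray) -> FeatureVector:
        if tm.kind == "GLCM":
            return _glcm_features(mat)
        axis = {"GLRLM": "run", "GLSZM": "zone", "GLDZM": "distance"}[tm.kind]
        return _run_zone_features(mat, tm.n_voxels, axis)

    if tm.aggregation == "per-direction-averaged" and tm.submatrices:
        per_dir = [one(m) for m in tm.submatrices if m.sum() > 0]
        fv = FeatureVector()
        for name in per_dir[0].names():
            vals = [d[name] for d in per_dir if name in d.values]
            if vals:
                fv.set(name, float(np.mean(vals)))
            else:
                fv.set(name, float("nan"), missing_reason="undefined-all-directions")
        return fv
    return one(tm.matrix)
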