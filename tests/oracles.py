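"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over voxels, pairs and
matrix entries, deliberately avoiding the vectorized code paths of the
package, so agreement is evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]
HALF_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def _in(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


# ---------------------------------------------------------------------------
# Matrix enumerators (levels: int grid, 0 outside ROI, 1..n inside)
# ---------------------------------------------------------------------------

def glcm_merged(levels: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    shape = levels.shape
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        for d in HALF_13:
            w = tuple(v[a] + d[a] for a in range(3))
            if _in(shape, w) and levels[w] > 0:
                m[levels[v] - 1, levels[w] - 1] += 1
                m[levels[w] - 1, levels[v] - 1] += 1
    return m


def glrlm_merged(levels: np.ndarray, n: int) -> np.ndarray:
    shape = levels.shape
    runs = []
    for d in HALF_13:
        for v in np.ndindex(shape):
            if levels[v] == 0:
                continue
            prev = tuple(v[a] - d[a] for a in range(3))
            if _in(shape, prev) and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = tuple(v[a] + d[a] for a in range(3))
            while _in(shape, w) and levels[w] == levels[v]:
                length += 1
                w = tuple(w[a] + d[a] for a in range(3))
            runs.append((levels[v], length))
    max_len = max(r[1] for r in runs)
    m = np.zeros((n, max_len))
    for lvl, length in runs:
        m[lvl - 1, length - 1] += 1
    return m


def _zones(levels: np.ndarray):
    """26-connected equal-level zones via BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in np.ndindex(shape):
        if levels[v] == 0 or seen[v]:
            continue
        lvl = levels[v]
        queue = deque([v])
        seen[v] = True
        members = []
        while queue:
            u = queue.popleft()
            members.append(u)
            for d in OFFSETS_26:
                w = tuple(u[a] + d[a] for a in range(3))
                if _in(shape, w) and not seen[w] and levels[w] == lvl:
                    seen[w] = True
                    queue.append(w)
        zones.append((lvl, members))
    return zones


def glszm(levels: np.ndarray, n: int) -> np.ndarray:
    zones = _zones(levels)
    max_size = max(len(mem) for _, mem in zones)
    m = np.zeros((n, max_size))
    for lvl, mem in zones:
        m[lvl - 1, len(mem) - 1] += 1
    return m


def _border_distance(levels: np.ndarray, v) -> int:
    """Chebyshev distance to the nearest non-ROI voxel or grid edge."""
    shape = levels.shape
    best = min(min(v[a] + 1, shape[a] - v[a]) for a in range(3))
    for w in np.ndindex(shape):
        if levels[w] == 0:
            d = max(abs(v[a] - w[a]) for a in range(3))
            best = min(best, d)
    return best


def gldzm(levels: np.ndarray, n: int) -> np.ndarray:
    zones = _zones(levels)
    entries = []
    for lvl, mem in zones:
        dmin = min(_border_distance(levels, v) for v in mem)
        entries.append((lvl, dmin))
    max_d = max(d for _, d in entries)
    m = np.zeros((n, max_d))
    for lvl, d in entries:
        m[lvl - 1, d - 1] += 1
    return m


def ngtdm(levels: np.ndarray, n: int):
    shape = levels.shape
    s = np.zeros(n)
    counts = np.zeros(n)
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        nb = [levels[tuple(v[a] + d[a] for a in range(3))]
              for d in OFFSETS_26
              if _in(shape, tuple(v[a] + d[a] for a in range(3)))
              and levels[tuple(v[a] + d[a] for a in range(3))] > 0]
        if not nb:
            continue
        s[levels[v] - 1] += abs(levels[v] - sum(nb) / len(nb))
        counts[levels[v] - 1] += 1
    return counts.reshape(-1, 1), s


def ngldm(levels: np.ndarray, n: int, alpha: int = 0) -> np.ndarray:
    shape = levels.shape
    entries = []
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        k = 0
        for d in OFFSETS_26:
            w = tuple(v[a] + d[a] for a in range(3))
            if _in(shape, w) and levels[w] > 0 and abs(levels[w] - levels[v]) <= alpha:
                k += 1
        entries.append((levels[v], k))
    max_k = max(k for _, k in entries)
    m = np.zeros((n, max_k + 1))
    for lvl, k in entries:
        m[lvl - 1, k] += 1
    return m


# ---------------------------------------------------------------------------
# Feature statistics, naive loops
# ---------------------------------------------------------------------------

def _xlog2(p):
    return p * math.log2(p) if p > 0 else 0.0


def glcm_features(counts: np.ndarray) -> dict:
    n = counts.shape[0]
    total = counts.sum()
    p = counts / total
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))
    out = {}
    out["joint-maximum"] = p.max()
    out["joint-energy"] = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    out["joint-entropy"] = -sum(_xlog2(p[i][j]) for i in range(n) for j in range(n))
    out["contrast"] = sum(p[i][j] * (i - j) ** 2 for i in range(n) for j in range(n))
    out["dissimilarity"] = sum(p[i][j] * abs(i - j) for i in range(n) for j in range(n))
    out["inverse-difference"] = sum(p[i][j] / (1 + abs(i - j))
                                    for i in range(n) for j in range(n))
    out["inverse-difference-moment"] = sum(p[i][j] / (1 + (i - j) ** 2)
                                           for i in range(n) for j in range(n))
    out["inverse-variance"] = sum(p[i][j] / (i - j) ** 2
                                  for i in range(n) for j in range(n) if i != j)
    if sigma2 > 0:
        out["correlation"] = sum(p[i][j] * (i + 1 - mu) * (j + 1 - mu)
                                 for i in range(n) for j in range(n)) / sigma2
    out["autocorrelation"] = sum(p[i][j] * (i + 1) * (j + 1)
                                 for i in range(n) for j in range(n))
    out["sum-average"] = sum(p[i][j] * (i + j + 2) for i in range(n) for j in range(n))
    for name, power in (("cluster-tendency", 2), ("cluster-shade", 3),
                        ("cluster-prominence", 4)):
        out[name] = sum(p[i][j] * (i + j + 2 - 2 * mu) ** power
                        for i in range(n) for j in range(n))
    return out


def run_zone_features(counts: np.ndarray, n_voxels: int, axis_name: str) -> dict:
    ni, nj = counts.shape
    ns = counts.sum()
    p = counts / ns
    short = {"run": "short-run", "zone": "small-zone",
             "distance": "small-distance"}[axis_name]
    long_ = {"run": "long-run", "zone": "large-zone",
             "distance": "large-distance"}[axis_name]
    out = {}
    out[f"{short}-emphasis"] = sum(p[i][j] / (j + 1) ** 2
                                   for i in range(ni) for j in range(nj))
    out[f"{long_}-emphasis"] = sum(p[i][j] * (j + 1) ** 2
                                   for i in range(ni) for j in range(nj))
    out["low-gray-level-emphasis"] = sum(p[i][j] / (i + 1) ** 2
                                         for i in range(ni) for j in range(nj))
    out["high-gray-level-emphasis"] = sum(p[i][j] * (i + 1) ** 2
                                          for i in range(ni) for j in range(nj))
    out[f"{short}-low-gray-level-emphasis"] = sum(
        p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ni) for j in range(nj))
    out[f"{short}-high-gray-level-emphasis"] = sum(
        p[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ni) for j in range(nj))
    out[f"{long_}-low-gray-level-emphasis"] = sum(
        p[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ni) for j in range(nj))
    out[f"{long_}-high-gray-level-emphasis"] = sum(
        p[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ni) for j in range(nj))
    out["gray-level-nonuniformity"] = sum(
        sum(counts[i][j] for j in range(nj)) ** 2 for i in range(ni)) / ns
    out[f"{axis_name}-nonuniformity"] = sum(
        sum(counts[i][j] for i in range(ni)) ** 2 for j in range(nj)) / ns
    out[f"{axis_name}-percentage"] = ns / n_voxels
    out[f"{axis_name}-entropy"] = -sum(_xlog2(p[i][j])
                                       for i in range(ni) for j in range(nj))
    mu_i = sum(p[i][j] * (i + 1) for i in range(ni) for j in range(nj))
    mu_j = sum(p[i][j] * (j + 1) for i in range(ni) for j in range(nj))
    out["gray-level-variance"] = sum(p[i][j] * (i + 1 - mu_i) ** 2
                                     for i in range(ni) for j in range(nj))
    out[f"{axis_name}-variance"] = sum(p[i][j] * (j + 1 - mu_j) ** 2
                                       for i in range(ni) for j in range(nj))
    if axis_name in ("zone", "distance"):
        out["inverse-variance"] = out[f"{short}-emphasis"]
    return out


def ngtdm_features(counts: np.ndarray, s: np.ndarray, n_voxels: int) -> dict:
    n = counts.shape[0]
    n_valid = counts.sum()
    pi = [counts[i][0] / n_valid for i in range(n)]
    present = [i for i in range(n) if pi[i] > 0]
    ngp = len(present)
    out = {}
    denom_coarse = sum(pi[i] * s[i] for i in range(n))
    if denom_coarse > 0:
        out["coarseness"] = 1.0 / denom_coarse
    if ngp > 1:
        out["contrast"] = (sum(pi[i] * pi[j] * (i - j) ** 2
                               for i in present for j in present)
                           / (ngp * (ngp - 1))) * sum(s) / n_valid
        denom_busy = sum(abs((i + 1) * pi[i] - (j + 1) * pi[j])
                         for i in present for j in present)
        if denom_busy > 0:
            out["busyness"] = denom_coarse / denom_busy
        out["complexity"] = sum(abs(i - j) * (pi[i] * s[i] + pi[j] * s[j])
                                / (pi[i] + pi[j])
                                for i in present for j in present) / n_valid
        if denom_coarse > 0:
            out["strength"] = sum((pi[i] + pi[j]) * (i - j) ** 2
                                  for i in present for j in present) / denom_coarse
    return out


def ngldm_features(counts: np.ndarray, n_voxels: int) -> dict:
    ni, nj = counts.shape
    ns = counts.sum()
    p = counts / ns
    out = {}
    out["low-dependence-emphasis"] = sum(p[i][j] / (j + 1) ** 2
                                         for i in range(ni) for j in range(nj))
    out["high-dependence-emphasis"] = sum(p[i][j] * (j + 1) ** 2
                                          for i in range(ni) for j in range(nj))
    out["low-gray-level-emphasis"] = sum(p[i][j] / (i + 1) ** 2
                                         for i in range(ni) for j in range(nj))
    out["high-gray-level-emphasis"] = sum(p[i][j] * (i + 1) ** 2
                                          for i in range(ni) for j in range(nj))
    out["low-dependence-low-gray-level-emphasis"] = sum(
        p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ni) for j in range(nj))
    out["low-dependence-high-gray-level-emphasis"] = sum(
        p[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ni) for j in range(nj))
    out["high-dependence-low-gray-level-emphasis"] = sum(
        p[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ni) for j in range(nj))
    out["high-dependence-high-gray-level-emphasis"] = sum(
        p[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ni) for j in range(nj))
    out["gray-level-nonuniformity"] = sum(
        sum(counts[i][j] for j in range(nj)) ** 2 for i in range(ni)) / ns
    out["dependence-count-nonuniformity"] = sum(
        sum(counts[i][j] for i in range(ni)) ** 2 for j in range(nj)) / ns
    out["dependence-count-entropy"] = -sum(_xlog2(p[i][j])
                                           for i in range(ni) for j in range(nj))
    mu_i = sum(p[i][j] * (i + 1) for i in range(ni) for j in range(nj))
    mu_j = sum(p[i][j] * (j + 1) for i in range(ni) for j in range(nj))
    out["gray-level-variance"] = sum(p[i][j] * (i + 1 - mu_i) ** 2
                                     for i in range(ni) for j in range(nj))
    out["dependence-count-variance"] = sum(p[i][j] * (j + 1 - mu_j) ** 2
                                           for i in range(ni) for j in range(nj))
    return out


def texture_features_bruteforce(levels: np.ndarray, n: int, kind: str) -> dict:
    """Matrix + features for one family, all by enumeration."""
    n_voxels = int((levels > 0).sum())
    if kind == "GLCM":
        return glcm_features(glcm_merged(levels, n))
    if kind == "GLRLM":
        return run_zone_features(glrlm_merged(levels, n), n_voxels, "run")
    if kind == "GLSZM":
        return run_zone_features(glszm(levels, n), n_voxels, "zone")
    if kind == "GLDZM":
        return run_zone_features(gldzm(levels, n), n_voxels, "distance")
    if kind == "NGTDM":
        counts, s = ngtdm(levels, n)
        return ngtdm_features(counts, s, n_voxels)
    if kind == "NGLDM":
        return ngldm_features(ngldm(levels, n), n_voxels)
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# Concordance / AUC by exhaustive pair counting
# ---------------------------------------------------------------------------

def cindex_bruteforce(pi, time, event) -> float:
    n = len(pi)
    conc = 0.0
    usable = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                usable += 1
                if pi[i] > pi[j]:
                    conc += 1.0
                elif pi[i] == pi[j]:
                    conc += 0.5
    return conc / usable


def auc_bruteforce(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
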