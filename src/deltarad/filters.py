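"""Spacing-aware image filters applied before feature extraction.

LoG: 3D Laplacian-of-Gaussian at a ladder of physical scales (mm), feeding
the first-order statistics group. Wavelet: a single-level undecimated
separable 3D transform (order-1 Coiflet by default) whose eight sub-bands
LLL..HHH feed the texture group. Sub-band letters are ordered (x, y, z),
i.e. array axes 0, 1, 2; L is the approximation (low-pass) branch.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.signal import fftconvolve

from .images import ImageVolume

#: Default LoG scale ladder in mm.
DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 5.0)

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _log_kernel(sigma_mm: float, spacing, truncate: float = 4.0) -> np.ndarray:
    """Analytic 3D LoG kernel sampled at voxel centers (mm units).

    The kernel mean is subtracted so it sums exactly to zero: a constant
    image maps to zero to floating-point precision.
    """
    half = [max(1, int(np.ceil(truncate * sigma_mm / s))) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = xx ** 2 + yy ** 2 + zz ** 2
    g = np.exp(-r2 / (2 * sigma_mm ** 2)) / (2 * np.pi * sigma_mm ** 2) ** 1.5
    kernel = g * (r2 - 3 * sigma_mm ** 2) / sigma_mm ** 4
    return kernel - kernel.mean()


def log_filter(img: ImageVolume, sigma_list_mm=DEFAULT_LOG_SIGMAS_MM) -> dict[str, ImageVolume]:
    """Laplacian of Gaussian at each sigma (mm), spacing-aware.

    Returns a dict keyed ``LoG-<sigma>mm``. Sigma is a physical scale, so
    anisotropic grids are filtered isotropically in world space. Edges use
    nearest-edge padding.
    """
    out = {}
    for sigma in sigma_list_mm:
        if sigma <= 0:
            raise ValueError("LoG sigma must be positive")
        kernel = _log_kernel(sigma, img.spacing)
        half = [k // 2 for k in kernel.shape]
        padded = np.pad(img.values, [(h, h) for h in half], mode="edge")
        filtered = fftconvolve(padded, kernel, mode="valid")
        out[f"LoG-{sigma:g}mm"] = img.with_values(filtered)
    return out


class WaveletSubbands:
    """Result of :func:`wavelet_filter`.

    ``bands`` maps sub-band labels (LLL..HHH) to volumes on the input grid.
    The raw (possibly padded) coefficients are kept so the transform can be
    inverted exactly.
    """

    def __init__(self, bands: dict[str, ImageVolume], coeffs: dict,
                 wavelet: str, orig_shape: tuple[int, ...]):
        self.bands = bands
        self._coeffs = coeffs
        self._wavelet = wavelet
        self._orig_shape = orig_shape

    def reconstruct(self) -> np.ndarray:
        """Invert the transform; recovers the input to float precision."""
        rec = pywt.iswtn([self._coeffs], self._wavelet)
        return rec[tuple(slice(0, n) for n in self._orig_shape)]


def _key_to_label(key: str) -> str:
    return "".join("L" if c == "a" else "H" for c in key)


def wavelet_filter(img: ImageVolume, wavelet: str = "coif1") -> WaveletSubbands:
    """Single-level undecimated 3D separable wavelet transform.

    Odd axes are edge-padded to even length for the stationary transform
    and the sub-bands cropped back to the input grid. The LLL band carries
    the low-pass filter gain (2^(3/2) for an orthonormal filter bank);
    H-containing bands of a constant image vanish.
    """
    values = img.values
    pads = [(0, n % 2) for n in values.shape]
    padded = np.pad(values, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    crop = tuple(slice(0, n) for n in values.shape)
    bands = {
        _key_to_label(key): img.with_values(arr[crop])
        for key, arr in coeffs.items()
    }
    return WaveletSubbands(bands, coeffs, wavelet, values.shape)
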