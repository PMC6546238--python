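"""Gray-level discretization for histogram and texture features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscretizationConfig:
    """How ROI intensities are binned into integer gray levels 1..n.

    mode
        ``fixed-bin-number``: the ROI intensity range is split into
        ``n_bins`` equal-width bins (the usual CT convention).
        ``fixed-bin-size``: bins of width ``bin_width`` anchored at the ROI
        minimum (the usual PET/SUV convention).
    The lowest bin edge is inclusive; the ROI maximum falls in the top bin.
    """

    mode: str = "fixed-bin-number"
    n_bins: int = 32
    bin_width: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-bin-number", "fixed-bin-size"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed-bin-number" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == "fixed-bin-size" and self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


#: Package defaults per modality: fixed bin number for CT, fixed bin size
#: (0.25 SUV) for PET.
DEFAULT_CT = DiscretizationConfig("fixed-bin-number", n_bins=32)
DEFAULT_PET = DiscretizationConfig("fixed-bin-size", bin_width=0.25)


def discretize(values: np.ndarray, disc: DiscretizationConfig) -> tuple[np.ndarray, int]:
    """Map ROI intensities to integer gray levels 1..n_levels.

    Returns (levels, n_levels). A constant ROI maps to a single level.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin = values.min()
    vmax = values.max()
    if disc.mode == "fixed-bin-number":
        if vmax == vmin:
            return np.ones(values.shape, dtype=np.int64), 1
        lv = np.floor(disc.n_bins * (values - vmin) / (vmax - vmin)).astype(np.int64) + 1
        np.clip(lv, 1, disc.n_bins, out=lv)
        return lv, disc.n_bins
    lv = np.floor((values - vmin) / disc.bin_width).astype(np.int64) + 1
    return lv, int(lv.max())
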