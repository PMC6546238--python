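"""Ordered feature containers with explicit missing-value bookkeeping.

Features whose definition degenerates on a given ROI (e.g. the correlation
of a constant region) are recorded as *missing with a reason* rather than
silently emitted as zero, so downstream penalized models can exclude them
listwise instead of learning from artifacts.
"""

from __future__ import annotations

import math


class FeatureVector:
    """Ordered map feature-name -> value, with per-name missing reasons.

    Names follow the grammar ``filter_family_statistic`` (filter omitted for
    unfiltered features), e.g. ``wavelet-LLH_GLSZM_inverse-variance``.
    """

    def __init__(self) -> None:
        self.values: dict[str, float] = {}
        self.missing: dict[str, str] = {}

    def set(self, name: str, value: float, missing_reason: str | None = None) -> None:
        if name in self.values or name in self.missing:
            raise KeyError(f"duplicate feature name {name!r}")
        if missing_reason is not None:
            self.missing[name] = missing_reason
        else:
            v = float(value)
            if math.isfinite(v):
                self.values[name] = v
            else:
                self.missing[name] = "non-finite"

    def update(self, other: "FeatureVector", prefix: str = "") -> None:
        for k, v in other.values.items():
            self.set(prefix + k, v)
        for k, r in other.missing.items():
            self.set(prefix + k, float("nan"), missing_reason=r)

    def names(self) -> list[str]:
        out = list(self.values)
        out.extend(k for k in self.missing if k not in self.values)
        return out

    def __getitem__(self, name: str) -> float:
        if name in self.values:
            return self.values[name]
        if name in self.missing:
            return float("nan")
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.values or name in self.missing

    def __len__(self) -> int:
        return len(self.values) + len(self.missing)

    def as_dict(self) -> dict[str, float]:
        """All features as a plain dict; missing features appear as NaN."""
        out = dict(self.values)
        for k in self.missing:
            out.setdefault(k, float("nan"))
        return out
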