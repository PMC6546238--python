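"""Delta features: the eight image sets per patient.

Each patient contributes per-time-point feature vectors (CT-scan1,
CT-scan2, PET-scan1, PET-scan2) and their absolute and relative
between-scan differences (CT-abs, CT-rel, PET-abs, PET-rel). Relative
deltas are fractions internally; multiply by 100 only at reporting time.
"""

from __future__ import annotations

from .featurevector import FeatureVector

IMAGE_SET_LABELS = ("CT-scan1", "CT-scan2", "PET-scan1", "PET-scan2",
                    "CT-abs", "CT-rel", "PET-abs", "PET-rel")


def _check_inventories(pre: FeatureVector, during: FeatureVector) -> list[str]:
    names = pre.names()
    if set(names) != set(during.names()):
        raise ValueError("pre and during feature inventories differ")
    return names


def delta_abs(pre: FeatureVector, during: FeatureVector) -> FeatureVector:
    """Absolute change: during - pre, elementwise. Missing propagates."""
    out = FeatureVector()
    for name in _check_inventories(pre, during):
        if name in pre.missing:
            out.set(name, float("nan"), missing_reason=pre.missing[name])
        elif name in during.missing:
            out.set(name, float("nan"), missing_reason=during.missing[name])
        else:
            out.set(name, during[name] - pre[name])
    return out


def delta_rel(pre: FeatureVector, during: FeatureVector) -> FeatureVector:
    """Relative change: (during - pre) / pre, as a fraction.

    A zero pre-treatment value makes the ratio undefined; the feature is
    emitted missing with reason ``zero-baseline`` rather than +/-inf.
    """
    out = FeatureVector()
    for name in _check_inventories(pre, during):
        if name in pre.missing:
            out.set(name, float("nan"), missing_reason=pre.missing[name])
        elif name in during.missing:
            out.set(name, float("nan"), missing_reason=during.missing[name])
        elif pre[name] == 0:
            out.set(name, float("nan"), missing_reason="zero-baseline")
        else:
            out.set(name, (during[name] - pre[name]) / pre[name])
    return out
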