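#!/usr/bin/env python
"""Preprocess all scans to the common grids and extract the eight
image-set feature tables (per-time-point plus absolute/relative deltas).

Writes one CSV per image set under results/features.
"""

from deltarad import FAST_CONFIG, build_image_set_tables

from _common import FEATURES_DIR, study_patients

if __name__ == "__main__":
    patients = study_patients()
    tables, excluded = build_image_set_tables(patients, FAST_CONFIG)
    FEATURES_DIR.mkdir(parents=True, exist_ok=True)
    for label, df in tables.items():
        df.to_csv(FEATURES_DIR / f"{label}.csv")
        print(f"{label}: {df.shape[0]} patients x {df.shape[1]} features")
    if excluded:
        print(f"excluded (split-segment rule): {excluded}")
    else:
        print("no patients excluded by the split-segment rule")
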