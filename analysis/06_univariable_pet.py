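#!/usr/bin/env python
"""Univariable Cox regression on the percentage variation of the common
PET metrics (volume, SUVmax, SUVmean, SUVpeak, MTV50%, TLG50%) between
the two scans, on the combined cohort.
"""

import pandas as pd

from deltarad import clinical_table, compute_pet_metrics, univariable_pet_metrics
from deltarad.pipeline import preprocess_patient

from _common import RESULTS, study_patients

if __name__ == "__main__":
    patients = study_patients()
    clin = clinical_table(patients)
    rows_pre, rows_during = {}, {}
    for p in patients:
        prep = preprocess_patient(p)
        if prep is None:
            continue
        rows_pre[p.patient_id] = compute_pet_metrics(
            prep.images[("PET", "scan1")], prep.masks[("PET", "scan1")])
        rows_during[p.patient_id] = compute_pet_metrics(
            prep.images[("PET", "scan2")], prep.masks[("PET", "scan2")])
    pre = pd.DataFrame.from_dict(rows_pre, orient="index").sort_index()
    during = pd.DataFrame.from_dict(rows_during, orient="index").sort_index()
    sub = clin.loc[pre.index]
    out = univariable_pet_metrics(pre, during, sub["survival_time"],
                                  sub["event"])
    path = RESULTS / "tables" / "univariable_pet.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path)
    print(out[["pct_change_mean", "hr", "hr_ci_low", "hr_ci_high",
               "p_value", "c_index"]].round(3))
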