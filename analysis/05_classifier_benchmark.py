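#!/usr/bin/env python
"""Two-year-survival classifier benchmark: five families x eight image
sets, repeated stratified splits, mean-AUC heatmap table.
Requires results/features (run 02 first).
"""

import numpy as np
import pandas as pd

from deltarad import classifier_benchmark, clinical_table
from deltarad.delta import IMAGE_SET_LABELS
from deltarad.synthetic import two_year_survival

from _common import FEATURES_DIR, RESULTS, STUDY_SEED, study_patients

if __name__ == "__main__":
    clin = clinical_table(study_patients())
    tables = {lbl: pd.read_csv(FEATURES_DIR / f"{lbl}.csv",
                               index_col="patient_id")
              for lbl in IMAGE_SET_LABELS}
    ty = pd.Series(two_year_survival(clin["survival_time"].to_numpy(),
                                     clin["event"].to_numpy()),
                   index=clin.index)
    n_undef = int(ty.isna().sum())
    res = classifier_benchmark(tables, ty, n_repetitions=15, seed=STUDY_SEED)
    out = RESULTS / "tables" / "classifier_heatmap.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    res.mean_auc.to_csv(out)
    best = res.mean_auc.stack().idxmax()
    print(f"excluded {n_undef} patients censored before two years")
    print(res.mean_auc.round(3))
    print(f"best mean AUC: {res.mean_auc.stack().max():.3f} "
          f"({best[0]} on {best[1]})")
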