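#!/usr/bin/env python
"""Penalized Cox model development and validation.

Median follow-up (reverse Kaplan-Meier), the train-on-one /
validate-on-the-rest c-index matrix over all eight image sets, the
combined 75/25 split, and per-cohort prognostic-index ranges.
Requires results/features (run 02 first).
"""

import pandas as pd

from deltarad import (clinical_table, combined_split_experiment,
                      cross_cohort_experiment, fit_lasso_cox,
                      km_median_followup, pi_range_summary, prognostic_index)
from deltarad.delta import IMAGE_SET_LABELS

from _common import FEATURES_DIR, RESULTS, STUDY_SEED, study_patients

if __name__ == "__main__":
    clin = clinical_table(study_patients())
    tables = {lbl: pd.read_csv(FEATURES_DIR / f"{lbl}.csv",
                               index_col="patient_id")
              for lbl in IMAGE_SET_LABELS}
    out_dir = RESULTS / "tables"
    out_dir.mkdir(parents=True, exist_ok=True)

    fu = km_median_followup(clin["survival_time"], clin["event"])
    print(f"median follow-up (reverse KM): {fu['median_followup']:.2f} y "
          f"[range {fu['min_time']:.2f}-{fu['max_time']:.2f}]")

    cross = cross_cohort_experiment(tables, clin, n_repeats=3,
                                    seed=STUDY_SEED)
    cross.to_csv(out_dir / "cross_cohort_cindex.csv", index=False)
    val = cross[cross["role"] == "validate"].dropna(subset=["c_index"])
    print(f"cross-cohort: {val['significant'].sum()}/{len(val)} validation "
          f"c-indices significantly above 0.5; "
          f"{int(cross['empty_model'].sum())} empty-model cells")

    combined = combined_split_experiment(tables, clin, train_frac=0.75,
                                         seed=STUDY_SEED, n_repeats=3)
    combined.to_csv(out_dir / "combined_split_cindex.csv", index=False)

    # prognostic-index spread for the first non-empty training model
    first = cross[(cross["role"] == "train") & (~cross["empty_model"])]
    if not first.empty:
        row = first.iloc[0]
        tr_idx = clin.index[clin["cohort"] == row["train_cohort"]]
        model = fit_lasso_cox(tables[row["image_set"]].loc[tr_idx],
                              clin.loc[tr_idx, "survival_time"],
                              clin.loc[tr_idx, "event"], n_repeats=3,
                              seed=STUDY_SEED)
        pi = prognostic_index(model, tables[row["image_set"]])
        ranges = pi_range_summary(pi, clin["cohort"])
        ranges.to_csv(out_dir / "pi_ranges.csv")
        print(f"PI ranges for {row['image_set']} trained on "
              f"{row['train_cohort']}:\n{ranges}")
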