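"""Shared configuration for the numbered analysis drivers.

The study is a scaled-down synthetic analogue of a four-cohort
multi-center NSCLC delta-radiomics dataset; every driver regenerates or
reloads it deterministically from STUDY_SEED.
"""

from pathlib import Path

from deltarad import SurvivalGroundTruth, default_study_specs, generate_cohort

STUDY_SEED = 1
N_SCALE = 0.5  # half-size cohorts (25/16/14/15 patients)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FEATURES_DIR = RESULTS / "features"

#: The outcome process: a modest volume-driven hazard so the prognostic
#: pipeline has a recoverable (but not overwhelming) signal to chase.
TRUTH = SurvivalGroundTruth(baseline_hazard_scale=0.5,
                            censoring_rate_target=0.25,
                            log_hazard_coefficients={"log_volume": 0.6})


def study_patients():
    specs = default_study_specs(n_scale=N_SCALE)
    patients = []
    for i, spec in enumerate(specs):
        patients.extend(generate_cohort(spec, TRUTH, seed=STUDY_SEED * 7 + i))
    return patients
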