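"""Shared configuration for the numbered analysis drivers.

The drivers exercise the four modelling steps on one paper-shaped
synthetic cohort (n=401, six true effects + 11 noise markers, ~28% event
fraction, 1.2-11% missingness).  Resampling runs at a desk scale of m=5
imputations x B=40 bootstrap draws; every stage derives its randomness
from MASTER_SEED, so later drivers can rebuild earlier stages exactly.
Outputs land in results/.
"""

from pathlib import Path

import tamrisk as tr

MASTER_SEED = 1
M, B = 5, 40
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

COHORT_CSV = RESULTS / "cohort.csv"
SCREENING_CSV = RESULTS / "screening.csv"
FORMS_JSON = RESULTS / "screened_forms.json"
STABILITY_CSV = RESULTS / "stability.csv"
FINAL_FORMS_JSON = RESULTS / "final_forms.json"
MODEL_CSV = RESULTS / "model.csv"
SCORES_CSV = RESULTS / "scores.csv"
EVAL_JSON = RESULTS / "evaluation.json"


def cohort_config():
    return tr.default_config()


def generating_model():
    return tr.calibrate_baseline(tr.default_generating_model(), cohort_config())


def covariate_names(cohort):
    skip = set(tr.cohort.OUTCOME_COLUMNS) | {"tam_duration"}
    return [c for c in cohort.columns if c not in skip]


def imputed_path(j: int) -> Path:
    return RESULTS / f"imputed_{j + 1}.csv"


def seed_for(stage: int) -> int:
    return (MASTER_SEED * 1000003 + stage) % (2**31)
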