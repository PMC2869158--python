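"""Step 1: univariate screening and risk-function selection.

Runs the FP -> minimum-p -> non-ordinal cascade on every candidate
variable of the simulated cohort (ordinal clinical covariates get the
linear-only screen) and writes the screening table plus the selected
forms (with frozen scaling / cutpoints / quartiles) for later stages.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import tamrisk as tr  # noqa: E402
from _common import COHORT_CSV, FORMS_JSON, SCREENING_CSV, covariate_names  # noqa: E402


def main() -> None:
    if not COHORT_CSV.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    cohort = tr.read_cohort(COHORT_CSV)
    covars = covariate_names(cohort)
    data = tr.SurvivalData(cohort["time_rfs"], cohort["event_rfs"],
                           cohort[covars].astype(float))
    results = tr.screen_all(data, covars, ordinal={"nodes", "grade"})
    table = tr.screening_table(results)
    table.to_csv(SCREENING_CSV, index=False)
    forms = {r.variable: r.form.to_dict() for r in results if r.selected}
    FORMS_JSON.write_text(json.dumps(forms, indent=2))

    sel = table[table.selected]
    print(f"screened {len(covars)} variables; {len(sel)} selected as candidates:")
    print(sel[["variable", "form", "n_available", "p_value", "method"]]
          .to_string(index=False))
    print(f"wrote {SCREENING_CSV} and {FORMS_JSON}")


if __name__ == "__main__":
    main()
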