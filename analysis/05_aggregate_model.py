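"""Step 4: final fits, Rubin pooling and aggregate risk scores.

Fits the refined variable set to each completed dataset, pools
coefficients and standard errors by Rubin's rules (hazard ratios for
raw-scale continuous biomarkers reported per 100 histoscore units), and
writes the per-patient aggregate / standardised risk scores with their
quartile risk groups.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402

import tamrisk as tr  # noqa: E402
from tamrisk.forms import Form  # noqa: E402
from _common import (FINAL_FORMS_JSON, M, MODEL_CSV, SCORES_CSV,  # noqa: E402
                     imputed_path)


def main() -> None:
    if not FINAL_FORMS_JSON.exists():
        raise SystemExit("run 04_stability.py first")
    final = {v: Form.from_dict(d) for v, d in
             json.loads(FINAL_FORMS_JSON.read_text()).items()}
    if not final:
        raise SystemExit("refined model is empty; nothing to aggregate")
    imputed = [pd.read_csv(imputed_path(j)) for j in range(M)]

    fits = tr.fit_final(imputed, final)
    per_100 = frozenset(v for v, f in final.items()
                        if f.kind == "linear" and v not in tr.CLINICAL_VARIABLES)
    model = tr.rubin_pool(fits, final, per_100=per_100)
    table = model.hazard_ratio_table()
    table.to_csv(MODEL_CSV)

    score, std = tr.aggregate_scores(fits, imputed, final)
    strat = tr.make_risk_groups(score, k=4)
    pd.DataFrame({"id": imputed[0]["id"], "score": score,
                  "standardised": std, "risk_group": strat.group}
                 ).to_csv(SCORES_CSV, index=False)

    print(f"final model over m={M} imputations "
          f"(per-100-unit HRs for: {sorted(per_100) or 'none'}):")
    print(table.round(4).to_string())
    print(f"\nrisk-group cutoffs (aggregate score): "
          f"{[round(c, 3) for c in strat.cutoffs]}")
    print(f"wrote {MODEL_CSV} and {SCORES_CSV}")


if __name__ == "__main__":
    main()
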