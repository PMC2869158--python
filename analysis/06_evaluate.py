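"""Model performance against the Nottingham Prognostic Index.

Compares the aggregated biomarker model with NPI on the simulated cohort:
Harrell's C-index, Nagelkerke R2, risk-group reclassification (quartile
model groups vs NPI quartile splits 3.3/4.2/4.8) and Kaplan-Meier
event-free rates at 3/5/7/10 years in each risk group.  Writes
results/evaluation.json and per-group KM step functions.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

import tamrisk as tr  # noqa: E402
from tamrisk.evaluation import km_curves  # noqa: E402
from _common import (COHORT_CSV, EVAL_JSON, M, RESULTS, SCORES_CSV,  # noqa: E402
                     imputed_path)


def main() -> None:
    if not SCORES_CSV.exists():
        raise SystemExit("run 05_aggregate_model.py first")
    cohort = tr.read_cohort(COHORT_CSV)
    scores = pd.read_csv(SCORES_CSV)
    imputed = [pd.read_csv(imputed_path(j)) for j in range(M)]
    t = cohort["time_rfs"].to_numpy(float)
    e = cohort["event_rfs"].to_numpy(int)

    npi = np.mean([tr.npi_score(d["size"], d["grade"], d["nodes"])
                   for d in imputed], axis=0)
    group_model = scores["risk_group"].to_numpy(int)
    group_npi_q = tr.npi_group(npi, "quartile")
    group_npi_std = tr.npi_group(npi, "standard")

    c_model = tr.harrell_c(scores["score"], t, e)
    c_npi = tr.harrell_c(npi, t, e)
    rec = tr.reclassify(group_model, group_npi_q, e)
    ef_model = tr.event_free_rate(group_model, t, e)
    ef_npi = tr.event_free_rate(group_npi_std, t, e)

    out = {
        "cindex": {"biomarker_model": c_model, "npi": c_npi},
        "reclassification": {
            "events": {"up": rec.up_events, "down": rec.down_events,
                       "net_gain_pct": rec.net_gain_events_pct, "p": rec.p_events},
            "event_free": {"up": rec.up_eventfree, "down": rec.down_eventfree,
                           "net_gain_pct": rec.net_gain_eventfree_pct,
                           "p": rec.p_eventfree},
        },
        "event_free_by_group_model": ef_model.to_dict(orient="index"),
        "event_free_by_group_npi_standard": ef_npi.to_dict(orient="index"),
    }
    EVAL_JSON.write_text(json.dumps(out, indent=2, default=float))
    km_curves(group_model, t, e).to_csv(RESULTS / "km_model_groups.csv", index=False)
    km_curves(group_npi_std, t, e).to_csv(RESULTS / "km_npi_groups.csv", index=False)

    print(f"C-index: biomarker model {100 * c_model:.0f}% vs NPI {100 * c_npi:.0f}%")
    print(f"reclassification net gain: events {rec.net_gain_events_pct:+.0f}% "
          f"(p={rec.p_events:.3f}), event-free {rec.net_gain_eventfree_pct:+.0f}% "
          f"(p={rec.p_eventfree:.3f})")
    low_m = ef_model.loc[1]
    low_n = ef_npi.loc[1]
    print(f"7-year event-free rate, lowest-risk group: model "
          f"{100 * low_m['7y']:.0f}% vs NPI {100 * low_n['7y']:.0f}%")
    print(f"wrote {EVAL_JSON}")


if __name__ == "__main__":
    main()
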