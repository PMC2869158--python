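"""Step 3: bootstrap stability refinement.

Re-checks threshold / non-ordinal forms on every bootstrap sample, runs
MFP backward elimination (variable removal at P=0.05, FP re-search of
continuous variables) on each of the m x B samples, and applies the 50%
reliability / form-stability rules.  Writes the inclusion-frequency table
(with the a/b verdict key) and the refined final forms.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402

import tamrisk as tr  # noqa: E402
from tamrisk.forms import Form  # noqa: E402
from tamrisk.imputation import build_sample_set  # noqa: E402
from tamrisk.stability import (fit_sample_models, inclusion_frequency,  # noqa: E402
                               refine, special_form_stability)
from _common import (B, FINAL_FORMS_JSON, FORMS_JSON, M, STABILITY_CSV,  # noqa: E402
                     imputed_path, seed_for)


def main() -> None:
    if not imputed_path(0).exists():
        raise SystemExit("run 03_impute_and_resample.py first")
    forms = {v: Form.from_dict(d) for v, d in
             json.loads(FORMS_JSON.read_text()).items()}
    imputed = [pd.read_csv(imputed_path(j)) for j in range(M)]
    samples = build_sample_set(imputed, B, seed_for(2))

    special = {v: f for v, f in forms.items()
               if f.kind in ("threshold", "non_ordinal")}
    spec_stab = special_form_stability(samples, special)
    stable = {v: s for v, s in spec_stab.items() if s >= 0.5}
    unstable = {v: s for v, s in spec_stab.items() if s < 0.5}
    for v, s in spec_stab.items():
        print(f"special form {v}: re-manifests in {100 * s:.0f}% of samples "
              f"({'stable' if s >= 0.5 else 'dropped as unstable'})")

    candidates = {v: f for v, f in forms.items() if v not in unstable}
    fp_search = frozenset(v for v, f in forms.items()
                          if f.kind in ("linear", "fp1", "fp2")
                          and v not in ("nodes", "grade"))
    models = fit_sample_models(samples, candidates, 0.05, fp_search)
    report = inclusion_frequency(models, list(candidates), forms,
                                 special_stability=stable, fp_search=fp_search,
                                 unstable_specials=unstable)
    report.to_frame().to_csv(STABILITY_CSV, index=False)
    final = refine(report, forms)
    FINAL_FORMS_JSON.write_text(json.dumps(
        {v: f.to_dict() for v, f in final.items()}, indent=2))

    print(f"\nfitted {len(models)} sample models "
          f"({sum(1 for m in models if m.flagged)} flagged)")
    print(report.to_frame().to_string(index=False))
    print(f"\nreliable-stable variables: {sorted(final) or 'none'}")
    print(f"wrote {STABILITY_CSV} and {FINAL_FORMS_JSON}")


if __name__ == "__main__":
    main()
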