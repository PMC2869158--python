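"""Bootstrap stability refinement (Step 3).

Each of the m x B sample datasets gets a multivariable fractional-
polynomial (MFP) model built by backward elimination: variables leave one
at a time by likelihood-ratio test at alpha 0.05 (largest p first), and
after elimination settles, every retained continuous variable entered as
linear is re-examined by the FP closed test (against the other retained
columns) and upgraded to FP1/FP2 when that significantly improves the fit;
any change restarts elimination.  Threshold / non-ordinal variables enter
as fixed 0/1 indicators whose form is never re-searched inside MFP — their
stability is assessed beforehand by re-running the corresponding scan on
each sample.

Refinement then applies the 50% rules: a variable retained in fewer than
half of the sample models is *unreliable*; a variable whose screened
special or polynomial form fails to re-manifest in at least half of the
relevant samples is *unstable*; only reliable-stable variables survive,
with their screened forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import forms as F
from .cox import ConvergenceError, CoxError, CoxFit, RankDeficiencyError, SurvivalData
from .imputation import SampleSet
from .screening import ScreeningConfig, _best_fp, closed_test_select, minp_scan, nonordinal_scan


@dataclass
class SampleModel:
    imp: int
    boot: int
    retained: list[str]
    forms: dict[str, F.Form]
    fit: CoxFit | None
    flagged: list[str] = field(default_factory=list)


@dataclass
class StabilityReport:
    inclusion_frequency: dict[str, float]
    form_stability: dict[str, float]
    verdicts: dict[str, str]
    n_models: int
    threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        key = {"unreliable": "a", "unstable-form": "b", "reliable-stable": ""}
        rows = []
        for v, f in self.inclusion_frequency.items():
            rows.append({
                "variable": v,
                "inclusion_frequency_pct": 100.0 * f if np.isfinite(f) else np.nan,
                "form_stability": self.form_stability.get(v, np.nan),
                "verdict": self.verdicts[v],
                "key": key[self.verdicts[v]],
            })
        return pd.DataFrame(rows)


def reassess_special_form(sample: pd.DataFrame, variable: str,
                          screened_form: F.Form,
                          config: ScreeningConfig = ScreeningConfig(),
                          time_col: str = "time_rfs",
                          event_col: str = "event_rfs") -> bool:
    """Does the screened threshold / non-ordinal effect re-manifest here?

    Re-runs the corresponding scan on the sample at the screening alpha.
    A threshold form counts as re-manifesting if the scan selects any
    cutpoint; a non-ordinal form must re-select the same quartile pattern.
    """
    if screened_form.kind not in ("threshold", "non_ordinal"):
        raise ValueError("reassessment applies to threshold/non_ordinal forms only")
    if sample[event_col].sum() < 2:
        return False
    data = SurvivalData(sample[time_col], sample[event_col],
                        sample[[variable]].astype(float))
    try:
        if screened_form.kind == "threshold":
            return minp_scan(data, variable, config).selected
        res = nonordinal_scan(data, variable, config)
        return bool(res.selected and res.form.pattern == screened_form.pattern)
    except CoxError:
        return False


def special_form_stability(samples: SampleSet, special_forms: dict[str, F.Form],
                           config: ScreeningConfig = ScreeningConfig(),
                           time_col: str = "time_rfs",
                           event_col: str = "event_rfs") -> dict[str, float]:
    """Fraction of all m x B samples in which each special form re-manifests."""
    counts = {v: 0 for v in special_forms}
    total = 0
    for _i, _b, sample in samples:
        total += 1
        for v, form in special_forms.items():
            if reassess_special_form(sample, v, form, config, time_col, event_col):
                counts[v] += 1
    return {v: c / total for v, c in counts.items()}


def _build_columns(df: pd.DataFrame, var: str, form: F.Form) -> np.ndarray:
    return F.form_columns(df[var].to_numpy(dtype=float), form)


def mfp_backward(sample: pd.DataFrame, candidates: dict[str, F.Form],
                 alpha_remove: float = 0.05,
                 fp_search: set[str] | frozenset[str] = frozenset(),
                 time_col: str = "time_rfs", event_col: str = "event_rfs",
                 imp: int = -1, boot: int = -1,
                 max_outer: int = 5) -> SampleModel:
    """Backward elimination with FP form search on one sample dataset.

    *candidates* maps variable -> initial form (special forms as frozen
    indicators; continuous variables typically linear).  Variables in
    *fp_search* may be upgraded to FP1/FP2 by the closed test at
    ``alpha_remove``.  Deterministic given the sample.  Non-convergent
    refits drop the diverging variable and flag the model; an empty final
    model is a valid outcome.
    """
    srt = SurvivalData(sample[time_col], sample[event_col])
    forms = dict(candidates)
    retained = list(candidates)
    flagged: list[str] = []

    def matrix(names, forms_):
        cols, slices, k = [], {}, 0
        for v in names:
            c = _build_columns(sample, v, forms_[v])
            slices[v] = slice(k, k + c.shape[1])
            k += c.shape[1]
            cols.append(c)
        X = np.column_stack(cols) if cols else np.empty((len(sample), 0))
        return X, slices

    def safe_fit(X, init=None):
        return srt.fit_matrix(X, init=init)

    def drop_failing(exc) -> None:
        # monotone likelihood or rank problem: drop the worst offender
        if isinstance(exc, ConvergenceError) and (
                exc.beta is not None or exc.bad_index is not None):
            _, slices = matrix(retained, forms)
            j = exc.bad_index if exc.bad_index is not None else int(
                np.argmax(np.abs(exc.beta)))
            victim = next(v for v, s in slices.items()
                          if s.start <= j < s.stop)
        else:
            victim = retained[-1]
        retained.remove(victim)
        flagged.append(f"dropped {victim}: {type(exc).__name__}")

    outer = 0
    changed = True
    full_fit = None
    while changed and outer < max_outer:
        outer += 1
        changed = False
        # --- backward elimination by LR test -------------------------------
        while retained:
            X, slices = matrix(retained, forms)
            try:
                full_fit = safe_fit(X)
            except CoxError as exc:
                drop_failing(exc)
                changed = True
                full_fit = None
                continue
            worst_p, worst_v = -1.0, None
            for v in retained:
                keep = np.ones(X.shape[1], dtype=bool)
                keep[slices[v]] = False
                dfree = int((~keep).sum())
                if keep.sum() == 0:
                    ll_red = srt.loglik_null
                else:
                    try:
                        red = safe_fit(X[:, keep], init=full_fit.coef[keep])
                        ll_red = red.loglik
                    except CoxError:
                        ll_red = -np.inf  # cannot remove v safely
                p = stats.chi2.sf(max(0.0, 2 * (full_fit.loglik - ll_red)), dfree)
                if p > worst_p:
                    worst_p, worst_v = p, v
            if worst_p > alpha_remove:
                retained.remove(worst_v)
                changed = True
            else:
                break
        if not retained:
            full_fit = None
            break
        # --- FP form search for retained continuous variables --------------
        for v in [v for v in retained if v in fp_search]:
            others = [w for w in retained if w != v]
            Xo, _ = matrix(others, forms)
            x = sample[v].to_numpy(dtype=float)
            shift, scale = F.default_scaling(x)
            if Xo.shape[1]:
                try:
                    adj_fit = srt.fit_matrix(Xo)
                    ll_null, adj_init = adj_fit.loglik, adj_fit.coef
                except CoxError:
                    continue
                adjust = Xo
            else:
                ll_null, adjust, adj_init = srt.loglik_null, None, None
            ll_lin, ll_fp1, bf1, ll_fp2, bf2 = _best_fp(
                srt, x, shift, scale, adjust, adj_init, F.FP_POWERS)
            choice, _ = closed_test_select(ll_null, ll_lin, ll_fp1, ll_fp2,
                                           alpha_remove)
            if choice is None:
                retained.remove(v)
                changed = True
            else:
                new_form = {"linear": F.linear(), "fp1": bf1, "fp2": bf2}[choice]
                if new_form.kind != forms[v].kind or new_form != forms[v]:
                    if new_form.kind != forms[v].kind:
                        changed = True
                    forms[v] = new_form
    if retained:
        X, _ = matrix(retained, forms)
        try:
            full_fit = srt.fit_matrix(X)
        except CoxError as exc:
            flagged.append(f"final fit failed: {type(exc).__name__}")
            full_fit = None
    names = []
    if retained and full_fit is not None:
        names = [n for v in retained for n in F.column_names(v, forms[v])]
        full_fit.names = names
    return SampleModel(imp=imp, boot=boot, retained=list(retained),
                       forms={v: forms[v] for v in retained},
                       fit=full_fit, flagged=flagged)


def fit_sample_models(samples: SampleSet, candidates: dict[str, F.Form],
                      alpha_remove: float = 0.05,
                      fp_search: set[str] | frozenset[str] = frozenset(),
                      time_col: str = "time_rfs", event_col: str = "event_rfs",
                      ) -> list[SampleModel]:
    """Run `mfp_backward` over every bootstrap sample (ordered, sequential)."""
    return [
        mfp_backward(sample, candidates, alpha_remove, fp_search,
                     time_col, event_col, imp=i, boot=b)
        for i, b, sample in samples
    ]


def inclusion_frequency(models: list[SampleModel],
                        candidates: list[str],
                        screened_forms: dict[str, F.Form],
                        special_stability: dict[str, float] | None = None,
                        fp_search: set[str] | frozenset[str] = frozenset(),
                        unstable_specials: dict[str, float] | None = None,
                        threshold: float = 0.5) -> StabilityReport:
    """Inclusion frequencies, form-stability fractions and 50%-rule verdicts.

    Polynomial form stability is computed over the models *retaining* the
    variable: the fraction whose final degree class (linear / fp1 / fp2)
    matches the screened class.  Special-form fractions are supplied by
    `special_form_stability` (computed over all samples).
    """
    if not models:
        raise ValueError("need at least one sample model")
    n = len(models)
    freq, form_stab, verdicts = {}, {}, {}
    for v in candidates:
        retaining = [m for m in models if v in m.retained]
        f = len(retaining) / n
        freq[v] = f
        stab = np.nan
        if special_stability and v in special_stability:
            stab = special_stability[v]
        elif v in fp_search and retaining:
            cls = screened_forms[v].degree_class
            stab = sum(m.forms[v].degree_class == cls for m in retaining) / len(retaining)
        form_stab[v] = stab
        if f < threshold:
            verdicts[v] = "unreliable"
        elif np.isfinite(stab) and stab < threshold:
            verdicts[v] = "unstable-form"
        else:
            verdicts[v] = "reliable-stable"
    for v, stab in (unstable_specials or {}).items():
        freq[v] = np.nan
        form_stab[v] = stab
        verdicts[v] = "unstable-form"
    return StabilityReport(inclusion_frequency=freq, form_stability=form_stab,
                           verdicts=verdicts, n_models=n, threshold=threshold)


def refine(report: StabilityReport,
           screened_forms: dict[str, F.Form]) -> dict[str, F.Form]:
    """Final variable set: reliable-stable variables with their screened forms."""
    return {v: screened_forms[v] for v, verdict in report.verdicts.items()
            if verdict == "reliable-stable"}
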