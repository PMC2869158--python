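"""Univariate screening and choice of risk-function form (Step 1).

Each candidate variable is screened through a three-stage cascade, with
the stage thresholds calibrated to a common family level of ~0.1:

1. fractional-polynomial closed test at alpha 0.1 — best FP2 against the
   null (4 df); if associated, FP2 vs linear (3 df), then FP2 vs best FP1
   (2 df), selecting the simplest adequate form;
2. minimum-p threshold scan at alpha 0.005 — the log-rank test at every
   candidate cutpoint (distinct values in the inner 80% of the empirical
   distribution, dichotomising as ``>= cut``), keeping the minimising cut
   (0.005 at the per-scan level corresponds to ~0.1 for the scan family);
3. non-ordinal quartile scan at alpha 0.025 (= 0.1/4 Bonferroni) — exactly
   four dichotomisations built from quartile ranges: R2, R3, R2+R3 and
   R1+R3 against the rest.

A variable selected at an earlier stage never reaches a later one.
Ordinal clinical covariates (too few distinct values for polynomials) are
screened by a plain linear univariate Cox LR test at alpha 0.1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import forms as F
from .cox import SurvivalData, logrank_cuts


@dataclass(frozen=True)
class ScreeningConfig:
    alpha_fp: float = 0.1
    alpha_minp: float = 0.005
    alpha_nonordinal: float = 0.025  # alpha_fp / 4
    minp_inner: float = 0.8  # central fraction of the distribution scanned
    fp_powers: tuple[float, ...] = F.FP_POWERS

    def __post_init__(self):
        for a in (self.alpha_fp, self.alpha_minp, self.alpha_nonordinal):
            if not 0 < a < 1:
                raise ValueError("alphas must be in (0, 1)")
        if not 0 < self.minp_inner <= 1:
            raise ValueError("minp_inner must be in (0, 1]")


@dataclass
class ScreeningResult:
    variable: str
    selected: bool
    form: F.Form | None
    p_value: float
    method: str  # fp | minp | nonordinal | linear
    n_available: int
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "selected": self.selected,
            "form": self.form.to_dict() if self.form else None,
            "p_value": self.p_value,
            "method": self.method,
            "n_available": self.n_available,
            "status": self.status,
        }


# re-exported here because form transforms are specified alongside screening
fp_transform = F.fp_transform


def _complete_case(data: SurvivalData, variable: str):
    x = data.design[variable].to_numpy(dtype=float)
    ok = ~np.isnan(x)
    sub = SurvivalData(data.time[ok], data.event[ok])
    return sub, x[ok]


def _best_fp(sub: SurvivalData, x: np.ndarray, shift: float, scale: float,
             adjust: np.ndarray | None, adjust_init: np.ndarray | None,
             powers: tuple[float, ...]):
    """Best FP1 and FP2 (max partial likelihood over the power set).

    Returns (ll_lin, ll_fp1, best_fp1, ll_fp2, best_fp2); *adjust* columns
    are included in every fit (None for univariate screening).
    """

    def fit_ll(cols: np.ndarray) -> float:
        X = cols if adjust is None else np.column_stack([cols, adjust])
        init = None
        if adjust_init is not None:
            init = np.r_[np.zeros(cols.shape[1]), adjust_init]
        try:
            return sub.fit_matrix(X, init=init).loglik
        except Exception:
            return -np.inf

    base = {p: F._power_col((x + shift) / scale, p) for p in powers}
    logz = np.log((x + shift) / scale)
    ll_lin = fit_ll(x[:, None])
    ll_fp1, best_fp1 = -np.inf, None
    for p in powers:
        ll = fit_ll(base[p][:, None])
        if ll > ll_fp1:
            ll_fp1, best_fp1 = ll, F.fp1(p, shift, scale)
    ll_fp2, best_fp2 = -np.inf, None
    for p1, p2 in itertools.combinations_with_replacement(powers, 2):
        c1 = base[p1]
        c2 = c1 * logz if p1 == p2 else base[p2]
        ll = fit_ll(np.column_stack([c1, c2]))
        if ll > ll_fp2:
            ll_fp2, best_fp2 = ll, F.fp2(p1, p2, shift, scale)
    return ll_lin, ll_fp1, best_fp1, ll_fp2, best_fp2


def closed_test_select(ll_null, ll_lin, ll_fp1, ll_fp2, alpha):
    """Decide null/linear/fp1/fp2 by the FP closed testing procedure.

    Returns (choice, p_assoc) where p_assoc is the association p-value of
    the chosen form against the null model.
    """
    p_assoc = stats.chi2.sf(max(0.0, 2 * (ll_fp2 - ll_null)), 4)
    if p_assoc >= alpha:
        return None, float(p_assoc)
    p_vs_lin = stats.chi2.sf(max(0.0, 2 * (ll_fp2 - ll_lin)), 3)
    if p_vs_lin >= alpha:
        return "linear", float(stats.chi2.sf(max(0.0, 2 * (ll_lin - ll_null)), 1))
    p_vs_fp1 = stats.chi2.sf(max(0.0, 2 * (ll_fp2 - ll_fp1)), 2)
    if p_vs_fp1 >= alpha:
        return "fp1", float(stats.chi2.sf(max(0.0, 2 * (ll_fp1 - ll_null)), 2))
    return "fp2", float(stats.chi2.sf(max(0.0, 2 * (ll_fp2 - ll_null)), 4))


def fp_closed_test(data: SurvivalData, variable: str,
                   config: ScreeningConfig = ScreeningConfig()) -> ScreeningResult:
    """Fractional-polynomial closed test for one continuous variable."""
    sub, x = _complete_case(data, variable)
    if np.unique(x).size < 10:
        return ScreeningResult(variable, False, None, np.nan, "fp", x.size,
                               status="skipped: <10 distinct values")
    shift, scale = F.default_scaling(x)
    ll_lin, ll_fp1, bf1, ll_fp2, bf2 = _best_fp(
        sub, x, shift, scale, None, None, config.fp_powers)
    choice, p = closed_test_select(sub.loglik_null, ll_lin, ll_fp1, ll_fp2,
                                   config.alpha_fp)
    if choice is None:
        return ScreeningResult(variable, False, None, p, "fp", x.size)
    form = {"linear": F.linear(), "fp1": bf1, "fp2": bf2}[choice]
    return ScreeningResult(variable, True, form, p, "fp", x.size)


def minp_candidate_cuts(x: np.ndarray, inner: float = 0.8) -> np.ndarray:
    """Distinct observed values inside the central *inner* fraction."""
    lo, hi = np.quantile(x, [(1 - inner) / 2, 1 - (1 - inner) / 2])
    cand = np.unique(x[(x >= lo) & (x <= hi)])
    # both groups must be non-empty under x >= cut
    return cand[(cand > x.min()) & (cand <= x.max())]


def minp_scan(data: SurvivalData, variable: str,
              config: ScreeningConfig = ScreeningConfig()) -> ScreeningResult:
    """Minimum-p-value threshold scan (maximally selected log-rank)."""
    sub, x = _complete_case(data, variable)
    cuts = minp_candidate_cuts(x, config.minp_inner)
    if cuts.size < 2:
        return ScreeningResult(variable, False, None, np.nan, "minp", x.size,
                               status="skipped: <2 candidate cutpoints")
    p = logrank_cuts(x, sub.time, sub.event, cuts)
    j = int(np.argmin(p))  # ties broken toward the smallest cut
    best_cut, p_min = float(cuts[j]), float(p[j])
    selected = p_min < config.alpha_minp
    form = F.threshold(best_cut) if selected else None
    return ScreeningResult(variable, selected, form, p_min, "minp", x.size)


def nonordinal_scan(data: SurvivalData, variable: str,
                    config: ScreeningConfig = ScreeningConfig()) -> ScreeningResult:
    """Four quartile-range dichotomisations; Bonferroni threshold 0.1/4."""
    sub, x = _complete_case(data, variable)
    q = tuple(float(v) for v in np.quantile(x, [0.25, 0.5, 0.75]))
    best_p, best_pat, skipped = np.inf, None, []
    for pat in F.NON_ORDINAL_PATTERNS:
        ind = F.pattern_indicator(x, pat, q)
        if ind.min() == ind.max():
            skipped.append(pat)
            continue
        p = float(logrank_cuts(ind, sub.time, sub.event, np.array([0.5]))[0])
        if p < best_p:
            best_p, best_pat = p, pat
    if best_pat is None:
        return ScreeningResult(variable, False, None, np.nan, "nonordinal", x.size,
                               status="skipped: degenerate quartiles")
    status = "ok" if not skipped else f"patterns skipped: {','.join(skipped)}"
    selected = best_p < config.alpha_nonordinal
    form = F.non_ordinal(best_pat, q) if selected else None
    return ScreeningResult(variable, selected, form, best_p, "nonordinal",
                           x.size, status=status)


def linear_screen(data: SurvivalData, variable: str,
                  config: ScreeningConfig = ScreeningConfig()) -> ScreeningResult:
    """Linear-only univariate Cox LR screen (ordinal clinical covariates)."""
    sub, x = _complete_case(data, variable)
    try:
        fit = sub.fit_matrix(x[:, None])
        p = float(stats.chi2.sf(max(0.0, 2 * (fit.loglik - fit.loglik_null)), 1))
    except Exception:
        return ScreeningResult(variable, False, None, np.nan, "linear", x.size,
                               status="skipped: degenerate fit")
    selected = p < config.alpha_fp
    return ScreeningResult(variable, selected, F.linear() if selected else None,
                           p, "linear", x.size)


def screen_all(data: SurvivalData, variables: list[str],
               config: ScreeningConfig = ScreeningConfig(),
               ordinal: set[str] | frozenset[str] = frozenset()) -> list[ScreeningResult]:
    """Run the fp -> minp -> non-ordinal cascade over *variables*.

    Each variable receives exactly one result; variables in *ordinal* get
    the linear-only screen instead of the cascade.
    """
    results = []
    for v in variables:
        if v in ordinal:
            results.append(linear_screen(data, v, config))
            continue
        res = fp_closed_test(data, v, config)
        if not res.selected:
            res = minp_scan(data, v, config)
        if not res.selected:
            res = nonordinal_scan(data, v, config)
        results.append(res)
    return results


def screening_table(results: list[ScreeningResult]) -> pd.DataFrame:
    """Report mirroring the screening-table layout: variable, form, n, p, method."""
    rows = []
    for r in results:
        form = "-"
        if r.form is not None:
            form = r.form.kind
            if r.form.kind == "fp1":
                form = f"fp1({r.form.powers[0]:g})"
            elif r.form.kind == "fp2":
                form = f"fp2({r.form.powers[0]:g},{r.form.powers[1]:g})"
            elif r.form.kind == "threshold":
                form = f"threshold(cut={r.form.cut:g})"
            elif r.form.kind == "non_ordinal":
                form = f"non_ordinal({r.form.pattern})"
        rows.append({"variable": r.variable, "selected": r.selected, "form": form,
                     "n_available": r.n_available, "p_value": r.p_value,
                     "method": r.method, "status": r.status})
    return pd.DataFrame(rows)
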