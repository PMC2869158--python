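"""Final model fitting, Rubin pooling and risk-group construction (Step 4).

The refined variable set is fitted once per imputed dataset (same design
columns in each); coefficients are pooled by Rubin's rules — pooled
coefficient = mean over imputations, pooled variance = mean within-
imputation variance + (1 + 1/m) x between-imputation variance — with
normal-approximation confidence intervals.  Each patient's aggregate risk
score is the mean of their linear predictors under the m fits, and risk
groups are empirical quantile splits of that score (quartiles for the
RFS-style model, tertiles when events are sparser), ties at a cutoff going
to the lower-risk group.

Hazard ratios for continuous biomarkers kept on the raw histoscore scale
are reported per 100 units; variables pre-scaled by their form (e.g. a
cubic-transformed score divided by 100) report on the documented
transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, SurvivalData
from .forms import Form
from .imputation import apply_forms


@dataclass
class AggregatedModel:
    variables: dict[str, Form]
    names: list[str]  # design-column names
    pooled_coef: np.ndarray
    pooled_se: np.ndarray
    per_imputation_fits: list[CoxFit]
    #: per-column scale factor applied when reporting hazard ratios
    hr_scale: np.ndarray

    @property
    def m(self) -> int:
        return len(self.per_imputation_fits)

    def hazard_ratio_table(self, ci: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + ci / 2)
        b, se, s = self.pooled_coef, self.pooled_se, self.hr_scale
        zval = b / se
        return pd.DataFrame(
            {
                "coef": b,
                "se": se,
                "HR": np.exp(s * b),
                "HR_lo": np.exp(s * (b - z * se)),
                "HR_hi": np.exp(s * (b + z * se)),
                "p": 2 * stats.norm.sf(np.abs(zval)),
                "hr_per_units": s,
            },
            index=pd.Index(self.names, name="term"),
        )

    def to_dict(self) -> dict:
        tab = self.hazard_ratio_table()
        return {
            "variables": {v: f.to_dict() for v, f in self.variables.items()},
            "terms": tab.reset_index().to_dict(orient="records"),
            "m": self.m,
        }


@dataclass
class RiskStratification:
    score: np.ndarray  # aggregate (mean over imputations) linear predictor
    standardised: np.ndarray  # z-scored aggregate score
    group: np.ndarray  # 1 = lowest risk .. k = highest
    cutoffs: np.ndarray
    k: int


def fit_final(imputed: list[pd.DataFrame], variables: dict[str, Form],
              time_col: str = "time_rfs", event_col: str = "event_rfs",
              ) -> list[CoxFit]:
    """One fit per completed dataset with identical design columns."""
    if not variables:
        raise ValueError("refined variable set is empty")
    fits = []
    for df in imputed:
        design = apply_forms(df, variables)
        data = SurvivalData(df[time_col], df[event_col], design)
        from .cox import fit_cox

        fits.append(fit_cox(data))
    names = fits[0].names
    if any(f.names != names for f in fits):
        raise ValueError("per-imputation fits have mismatched design columns")
    return fits


def rubin_pool(fits: list[CoxFit], variables: dict[str, Form] | None = None,
               per_100: set[str] | frozenset[str] = frozenset()) -> AggregatedModel:
    """Pool m Cox fits by Rubin's rules.

    *per_100* names raw-scale continuous variables whose hazard ratios are
    reported per 100 units of the covariate.
    """
    if not fits:
        raise ValueError("need at least one fit")
    names = fits[0].names
    if any(f.names != names for f in fits):
        raise ValueError("coefficient names differ across fits")
    m = len(fits)
    coefs = np.array([f.coef for f in fits])
    within = np.array([np.diag(f.cov) for f in fits]).mean(axis=0)
    qbar = coefs.mean(axis=0)
    between = coefs.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = within + (1 + 1 / m) * between
    hr_scale = np.array([100.0 if nm in per_100 else 1.0 for nm in names])
    return AggregatedModel(
        variables=dict(variables or {}),
        names=list(names),
        pooled_coef=qbar,
        pooled_se=np.sqrt(total),
        per_imputation_fits=list(fits),
        hr_scale=hr_scale,
    )


def aggregate_scores(fits: list[CoxFit], imputed: list[pd.DataFrame],
                     variables: dict[str, Form]) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient aggregate and standardised risk scores.

    The aggregate score is the mean over imputations j of the linear
    predictor of fit j evaluated on completed dataset j; the standardised
    score is its z-score over patients.
    """
    if len(fits) != len(imputed):
        raise ValueError("fits and imputed datasets must align")
    lps = []
    for fit, df in zip(fits, imputed):
        X = apply_forms(df, variables)
        if list(X.columns) != fit.names:
            raise ValueError("design columns do not match fit")
        lps.append(X.to_numpy(dtype=float) @ fit.coef)
    score = np.mean(lps, axis=0)
    sd = score.std()
    standardised = (score - score.mean()) / (sd if sd > 0 else 1.0)
    return score, standardised


def make_risk_groups(scores: np.ndarray, k: int = 4) -> RiskStratification:
    """Quantile risk groups 1 (lowest) .. k; ties at a cutoff go lower."""
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(scores).size < k:
        raise ValueError(f"need at least {k} distinct score values")
    cutoffs = np.quantile(scores, np.arange(1, k) / k)
    group = 1 + np.searchsorted(cutoffs, scores, side="left")
    sd = scores.std()
    return RiskStratification(
        score=scores,
        standardised=(scores - scores.mean()) / (sd if sd > 0 else 1.0),
        group=group.astype(int),
        cutoffs=cutoffs,
        k=k,
    )
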