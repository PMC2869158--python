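"""Model performance: NPI scoring, C-index, Nagelkerke R2, reclassification.

The Nottingham Prognostic Index is 0.2 x tumour size (cm) + grade (1-3) +
nodal stage (1-3); the standard grouping uses <3.4 / 3.4-5.4 / >5.4 and,
for a like-for-like comparison with a quartile-grouped biomarker model,
a quartile split at 3.3 / 4.2 / 4.8 is also supported.

Harrell's C counts censoring-comparable pairs (the earlier time must be an
event; tied times are non-comparable) with half credit for tied scores.
Nagelkerke R2 is the max-rescaled Cox-Snell likelihood-ratio R2.  The
reclassification analysis cross-tabulates standard-model and new-model
risk groups separately for event and event-free patients: among events an
upward move is an improvement, among event-free patients a downward move
is; significance among movers by an exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, km_estimate

NPI_STANDARD_CUTS = (3.4, 5.4)  # <3.4 low, 3.4-5.4 intermediate, >5.4 high
NPI_QUARTILE_CUTS = (3.3, 4.2, 4.8)


def npi_score(size, grade, nodes) -> np.ndarray:
    """Nottingham Prognostic Index: 0.2*size(cm) + grade + nodal stage."""
    size = np.asarray(size, dtype=float)
    grade = np.asarray(grade, dtype=float)
    nodes = np.asarray(nodes, dtype=float)
    if np.any(size <= 0):
        raise ValueError("tumour size must be positive")
    for name, v in (("grade", grade), ("nodal stage", nodes)):
        if not np.isin(v, (1, 2, 3)).all():
            raise ValueError(f"{name} must be in {{1, 2, 3}}")
    return 0.2 * size + grade + nodes


def npi_group(values, scheme: str = "standard",
              cutoffs: tuple[float, ...] | None = None) -> np.ndarray:
    """Group labels 1 (lowest risk) .. k; values at a cutoff go lower.

    Schemes: ``standard`` (<3.4 / 3.4-5.4 / >5.4), ``quartile``
    (3.3/4.2/4.8 -> 4 groups), ``tertile`` (empirical tertiles -> 3 groups),
    or explicit *cutoffs*.
    """
    values = np.asarray(values, dtype=float)
    if cutoffs is None:
        if scheme == "standard":
            # standard low group is strictly below 3.4
            return (1 + (values >= NPI_STANDARD_CUTS[0]).astype(int)
                    + (values > NPI_STANDARD_CUTS[1]).astype(int))
        if scheme == "quartile":
            cutoffs = NPI_QUARTILE_CUTS
        elif scheme == "tertile":
            cutoffs = tuple(np.quantile(values, [1 / 3, 2 / 3]))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return 1 + np.searchsorted(np.asarray(cutoffs, float), values, side="left")


def harrell_c(scores, time, event) -> float:
    """Harrell's concordance index over censoring-comparable pairs.

    Higher score must predict earlier event; tied scores get half credit;
    tied times are non-comparable.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    # pair (i, j) comparable iff t_i < t_j and subject i had the event
    ti = time[:, None]
    comp = (ti < time[None, :]) & (event[:, None] == 1)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no censoring-comparable pairs")
    si = scores[:, None]
    concordant = int((comp & (si > scores[None, :])).sum())
    tied = int((comp & (si == scores[None, :])).sum())
    return (concordant + 0.5 * tied) / n_comp


def nagelkerke_r2(fit: CoxFit) -> float:
    """Max-rescaled Cox-Snell R2 from the fit's log-likelihoods."""
    n = fit.n
    if n == 0:
        raise ValueError("empty fit")
    r2_cs = 1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / n)
    denom = 1.0 - np.exp(2.0 * fit.loglik_null / n)
    if denom <= 0:
        return 0.0
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


@dataclass
class ReclassificationResult:
    events_table: pd.DataFrame  # standard group x new group, event cases
    eventfree_table: pd.DataFrame
    up_events: int
    down_events: int
    net_gain_events_pct: float  # (up - down) / n_events * 100
    p_events: float
    up_eventfree: int
    down_eventfree: int
    net_gain_eventfree_pct: float  # (down - up) / n_eventfree * 100
    p_eventfree: float


def _cross(std, new, k):
    idx = pd.Index(range(1, k + 1))
    tab = pd.crosstab(pd.Categorical(std, categories=idx),
                      pd.Categorical(new, categories=idx), dropna=False)
    tab.index.name, tab.columns.name = "standard", "new"
    return tab


def _mover_p(up: int, down: int) -> float:
    if up + down == 0:
        return 1.0
    return float(stats.binomtest(up, up + down, 0.5).pvalue)


def reclassify(new_groups, std_groups, event_status) -> ReclassificationResult:
    """Risk-group reclassification of the new model against the standard one."""
    new_groups = np.asarray(new_groups).astype(int)
    std_groups = np.asarray(std_groups).astype(int)
    event_status = np.asarray(event_status).astype(int)
    if not (len(new_groups) == len(std_groups) == len(event_status)):
        raise ValueError("mismatched lengths")
    k = int(max(new_groups.max(), std_groups.max()))
    ev = event_status == 1
    up = new_groups > std_groups
    down = new_groups < std_groups
    n_ev, n_free = int(ev.sum()), int((~ev).sum())
    up_ev, down_ev = int((up & ev).sum()), int((down & ev).sum())
    up_free, down_free = int((up & ~ev).sum()), int((down & ~ev).sum())
    return ReclassificationResult(
        events_table=_cross(std_groups[ev], new_groups[ev], k),
        eventfree_table=_cross(std_groups[~ev], new_groups[~ev], k),
        up_events=up_ev,
        down_events=down_ev,
        net_gain_events_pct=100.0 * (up_ev - down_ev) / n_ev if n_ev else np.nan,
        p_events=_mover_p(up_ev, down_ev),
        up_eventfree=up_free,
        down_eventfree=down_free,
        net_gain_eventfree_pct=100.0 * (down_free - up_free) / n_free if n_free else np.nan,
        p_eventfree=_mover_p(down_free, up_free),
    )


def event_free_rate(groups, time, event,
                    horizons=(3.0, 5.0, 7.0, 10.0)) -> pd.DataFrame:
    """Kaplan-Meier event-free rates per risk group at fixed horizons.

    Horizons beyond a group's last follow-up are reported as NaN (flagged,
    not fatal); empty groups yield an all-NaN row.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    rows = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            rows[g] = [np.nan] * len(horizons)
            continue
        km = km_estimate(time[sel], event[sel])
        vals = []
        for h in horizons:
            vals.append(km.survival_at(h) if h <= km.max_follow_up else np.nan)
        rows[g] = vals
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"{h:g}y" for h in horizons])
    out.index.name = "group"
    return out.sort_index()


def km_curves(groups, time, event) -> pd.DataFrame:
    """Per-group KM step functions as a long table (group, time, survival, at_risk)."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    frames = []
    for g in np.unique(groups):
        sel = groups == g
        km = km_estimate(time[sel], event[sel])
        frames.append(pd.DataFrame({
            "group": g, "time": km.times, "survival": km.survival,
            "at_risk": km.at_risk, "events": km.n_events,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "time", "survival", "at_risk", "events"])
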