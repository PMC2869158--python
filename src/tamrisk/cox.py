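"""Proportional-hazards kernel: Cox fitting, LR/log-rank tests, Kaplan-Meier.

The partial-likelihood maximiser is written against numba because the
resampling stages of the pipeline fit on the order of 10^5 Cox models;
Newton-Raphson with step-halving, Efron handling of tied event times,
convergence on relative log-likelihood change (1e-9, max 100 iterations)
and divergence detection for monotone likelihoods.  Kaplan-Meier and the
k-group log-rank test are delegated to lifelines; a vectorised two-group
log-rank over many cutpoints (`logrank_cuts`) supports the minimum-p scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats


class CoxError(ValueError):
    """Base class for fitting failures (never silent garbage)."""


class RankDeficiencyError(CoxError):
    pass


class NoEventsError(CoxError):
    pass


class ConvergenceError(CoxError):
    """Raised on monotone likelihood / failure to converge."""

    def __init__(self, msg: str, beta: np.ndarray | None = None,
                 bad_index: int | None = None):
        super().__init__(msg)
        self.beta = beta
        self.bad_index = bad_index


@njit(cache=True)
def _efron_lgh(Xs, ts, es, beta, want_deriv):  # pragma: no cover - numba
    """Efron log partial likelihood with gradient and information matrix.

    Arrays must be sorted by ascending time; the risk set at an event time
    is the suffix starting at the first row of its tie group.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S = 0.0
    Sx = np.zeros(p)
    Sxx = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        t = ts[i]
        j0 = i
        while j0 >= 0 and ts[j0] == t:
            j0 -= 1
        j0 += 1
        d = 0
        sd = 0.0
        sdx = np.zeros(p)
        sdxx = np.zeros((p, p))
        for j in range(j0, i + 1):
            wj = w[j]
            S += wj
            for a in range(p):
                xa = Xs[j, a]
                Sx[a] += wj * xa
                if want_deriv:
                    for b in range(a, p):
                        Sxx[a, b] += wj * xa * Xs[j, b]
            if es[j] == 1:
                d += 1
                sd += wj
                ll += eta[j]
                if want_deriv:
                    for a in range(p):
                        xa = Xs[j, a]
                        grad[a] += xa
                        sdx[a] += wj * xa
                        for b in range(a, p):
                            sdxx[a, b] += wj * xa * Xs[j, b]
        if d > 0:
            for l in range(d):
                f = l / d
                denom = S - f * sd
                ll -= np.log(denom)
                if want_deriv:
                    for a in range(p):
                        za = (Sx[a] - f * sdx[a]) / denom
                        grad[a] -= za
                        for b in range(a, p):
                            zb = (Sx[b] - f * sdx[b]) / denom
                            hess[a, b] += (Sxx[a, b] - f * sdxx[a, b]) / denom - za * zb
        i = j0 - 1
    if want_deriv:
        for a in range(p):
            for b in range(a):
                hess[a, b] = hess[b, a]
    return ll, grad, hess


@njit(cache=True)
def _newton(Xs, ts, es, beta0, tol, maxiter):  # pragma: no cover - numba
    """Newton-Raphson with step-halving. Status: 0 ok, 2 diverged, 3 maxiter."""
    beta = beta0.copy()
    ll, grad, hess = _efron_lgh(Xs, ts, es, beta, True)
    status = 3
    niter = 0
    for it in range(maxiter):
        niter = it + 1
        step = np.linalg.solve(hess, grad)
        ok = False
        nll, ngrad, nhess = ll, grad, hess
        nb = beta
        for _h in range(30):
            nb = beta + step
            nll, ngrad, nhess = _efron_lgh(Xs, ts, es, nb, True)
            if np.isfinite(nll) and nll >= ll - 1e-12:
                ok = True
                break
            step = step * 0.5
        if not ok:
            status = 2
            break
        rel = abs(nll - ll) / (abs(ll) + 1.0)
        beta, ll, grad, hess = nb, nll, ngrad, nhess
        if np.max(np.abs(beta)) > 40.0:
            status = 2
            break
        if rel < tol:
            status = 0
            break
    return beta, ll, grad, hess, status, niter


@dataclass
class CoxFit:
    """Maximum partial-likelihood fit of a proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik_null: float
    loglik: float
    n_events: int
    n: int
    n_iter: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def k(self) -> int:
        return len(self.coef)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratios,
                "p": self.pvalues,
            },
            index=pd.Index(self.names, name="variable"),
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "loglik_null": self.loglik_null,
            "loglik": self.loglik,
            "n_events": int(self.n_events),
            "n": int(self.n),
        }


class SurvivalData:
    """Right-censored survival outcome with a named design matrix.

    Sorting and the null log-likelihood are precomputed once so that many
    models over column subsets of the same rows can be fitted cheaply
    (`fit_matrix` accepts arbitrary design matrices aligned to the original
    row order).
    """

    def __init__(self, time, event, design: pd.DataFrame | None = None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be aligned 1-d arrays")
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        self.time = time
        self.event = event.astype(np.int64)
        self.n = time.size
        self.n_events = int(self.event.sum())
        self.design = design
        if design is not None:
            if len(design) != self.n:
                raise ValueError("design rows must match outcome length")
            if design.columns.duplicated().any():
                raise ValueError("design column names must be unique")
        self._order = np.argsort(time, kind="stable")
        self._ts = np.ascontiguousarray(time[self._order])
        self._es = np.ascontiguousarray(self.event[self._order])
        self._ll0: float | None = None

    @property
    def loglik_null(self) -> float:
        if self._ll0 is None:
            ll, _, _ = _efron_lgh(
                np.zeros((self.n, 1)), self._ts, self._es, np.zeros(1), False
            )
            self._ll0 = float(ll)
        return self._ll0

    def fit_matrix(
        self,
        X: np.ndarray,
        names: list[str] | None = None,
        init: np.ndarray | None = None,
        tol: float = 1e-9,
        maxiter: int = 100,
    ) -> CoxFit:
        """Fit a Cox model with design *X* (rows in original order)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if n != self.n:
            raise ValueError("design rows must match outcome length")
        if self.n_events < 2:
            raise NoEventsError("need at least 2 events to fit")
        if not np.all(np.isfinite(X)):
            raise ValueError("design contains non-finite values")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            j = int(np.argmin(sd))
            raise RankDeficiencyError(f"constant design column (index {j})")
        Xs = np.ascontiguousarray(X[self._order])
        beta0 = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
        try:
            beta, ll, grad, hess, status, niter = _newton(
                Xs, self._ts, self._es, beta0, tol, maxiter
            )
        except Exception as exc:  # singular information inside Newton step
            if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
                raise RankDeficiencyError("design matrix is rank deficient") from exc
            raise ConvergenceError(f"Newton step failed: {exc}") from exc
        if status == 2 or np.max(np.abs(beta)) > 40.0:
            raise ConvergenceError(
                "coefficient divergence (monotone partial likelihood)", beta=beta
            )
        if status == 3:
            raise ConvergenceError("maximum iterations exceeded", beta=beta)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError("singular information at optimum") from exc
        if np.any(np.diag(cov) <= 0):
            raise ConvergenceError("information matrix not positive definite", beta=beta)
        # monotone likelihood flattens before the divergence bound: flag fits
        # whose per-SD log-hazard ratio is estimated with absurd uncertainty
        se_sd = np.sqrt(np.diag(cov)) * sd
        if np.any(se_sd > 5.0):
            raise ConvergenceError(
                "effectively infinite coefficient (monotone partial likelihood)",
                beta=beta, bad_index=int(np.argmax(se_sd)),
            )
        return CoxFit(
            names=list(names) if names is not None else [f"x{i}" for i in range(p)],
            coef=beta,
            cov=cov,
            loglik_null=self.loglik_null,
            loglik=float(ll),
            n_events=self.n_events,
            n=self.n,
            n_iter=niter,
        )

    def loglik_of(self, X: np.ndarray, beta: np.ndarray) -> float:
        """Partial log-likelihood at a fixed coefficient vector."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs = np.ascontiguousarray(X[self._order])
        ll, _, _ = _efron_lgh(Xs, self._ts, self._es, np.asarray(beta, float), False)
        return float(ll)


def fit_cox(data: SurvivalData, columns: list[str] | None = None, **kw) -> CoxFit:
    """Fit the Cox model on `data.design` (optionally a column subset)."""
    if data.design is None:
        raise ValueError("SurvivalData has no design matrix")
    design = data.design if columns is None else data.design[list(columns)]
    return data.fit_matrix(design.to_numpy(dtype=float), list(design.columns), **kw)


def lr_test(nested: CoxFit, full: CoxFit, df: int | None = None) -> float:
    """Likelihood-ratio p-value for nested Cox fits on the same data."""
    if not set(nested.names) <= set(full.names):
        raise ValueError("nested model's columns must be a subset of the full model's")
    if df is None:
        df = full.k - nested.k
    if df <= 0:
        raise ValueError("full model must have more free parameters")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6 * max(1.0, abs(full.loglik)):
        raise ValueError("full model log-likelihood below nested model: fit inconsistency")
    return float(stats.chi2.sf(max(stat, 0.0), df))


def lr_test_vs_null(fit: CoxFit) -> float:
    """LR p-value of a fit against the null (no-covariate) model."""
    stat = max(0.0, 2.0 * (fit.loglik - fit.loglik_null))
    return float(stats.chi2.sf(stat, fit.k))


@dataclass
class KMEstimate:
    """Product-limit estimate with its risk-set table."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        """Right-continuous step-function evaluation of S(t)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:  # no events: S(t) = 1 everywhere
            out = np.ones_like(t, dtype=float)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return float(out) if out.ndim == 0 else out

    @property
    def max_follow_up(self) -> float:
        return float(self._tmax)

    _tmax: float = field(default=np.nan, repr=False)


def km_estimate(time, event) -> KMEstimate:
    """Kaplan-Meier estimator (via lifelines) with risk-set bookkeeping."""
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("need at least one subject")
    if np.any(time < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter().fit(time, event)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    est = KMEstimate(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n_events=ev["observed"].to_numpy(dtype=float),
    )
    est._tmax = float(time.max())
    return est


def logrank_test(time, event, group) -> float:
    """k-group log-rank test p-value (lifelines), label-permutation invariant."""
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    if np.unique(group).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if event.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(time, group, event)
    return float(res.p_value)


def logrank_cuts(x, time, event, cuts) -> np.ndarray:
    """Two-group log-rank p-values for every dichotomisation ``x >= cut``.

    Vectorised over cutpoints: one O(n * n_cuts) pass instead of n_cuts
    separate log-rank computations.  Degenerate cuts (one empty group or
    zero variance) get p = 1.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    cuts = np.asarray(cuts, dtype=float)
    n = x.size
    order = np.argsort(time, kind="stable")
    ts, es, xs = time[order], event[order], x[order]
    Z = (xs[:, None] >= cuts[None, :]).astype(float)  # (n, C)
    # suffix sums: SZ[i] = sum_{j >= i} Z[j]; EZ likewise event-weighted
    SZ = np.zeros((n + 1, Z.shape[1]))
    SZ[:-1] = Z[::-1].cumsum(axis=0)[::-1]
    EZ = np.zeros_like(SZ)
    EZ[:-1] = (Z * es[:, None])[::-1].cumsum(axis=0)[::-1]
    # tie groups of event times
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    ends = np.r_[starts[1:], n]
    U = np.zeros(Z.shape[1])
    V = np.zeros(Z.shape[1])
    for s, e in zip(starts, ends):
        d = int(es[s:e].sum())
        if d == 0:
            continue
        nR = n - s
        n1R = SZ[s]
        O1 = EZ[s] - EZ[e]
        frac = n1R / nR
        U += O1 - d * frac
        if nR > 1:
            V += d * frac * (1.0 - frac) * (nR - d) / (nR - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), 0.0)
    p = stats.chi2.sf(chi2, 1)
    p[V <= 0] = 1.0
    return p
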