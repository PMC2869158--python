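import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from tamrisk.cox import (ConvergenceError, RankDeficiencyError, SurvivalData,
                         _efron_lgh, fit_cox, km_estimate, logrank_cuts,
                         logrank_test, lr_test, lr_test_vs_null)
from .conftest import make_survival

# 6-subject two-covariate-free fixture: distinct times, mixed censoring
FIX_TIME = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
FIX_EVENT = np.array([1, 0, 1, 1, 0, 1])
FIX_X = np.array([0.5, 1.2, -0.3, 0.8, 2.0, -1.0])


def hand_partial_loglik(beta, time, event, x):
    """Independent hand-written partial likelihood (distinct times only)."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestFitCox:
    def test_constant_column_is_rank_deficient(self, rng):
        t, e = make_survival(40, rng)
        data = SurvivalData(t, e)
        with pytest.raises(RankDeficiencyError):
            data.fit_matrix(np.ones((40, 1)))

    def test_duplicate_columns_rejected(self, rng):
        t, e = make_survival(60, rng)
        x = rng.normal(size=60)
        with pytest.raises((RankDeficiencyError, ConvergenceError)):
            SurvivalData(t, e).fit_matrix(np.column_stack([x, x]))

    def test_matches_bruteforce_partial_likelihood(self):
        """Newton optimum agrees with grid/1-d maximisation of the hand-written
        partial likelihood to 1e-6 on the 6-subject fixture."""
        fit = SurvivalData(FIX_TIME, FIX_EVENT).fit_matrix(FIX_X[:, None])
        res = minimize_scalar(
            lambda b: -hand_partial_loglik(b, FIX_TIME, FIX_EVENT, FIX_X),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert abs(fit.coef[0] - res.x) < 1e-6
        assert np.isclose(fit.loglik, -res.fun, atol=1e-9)

    def test_recovers_true_log_hazard_ratio(self, rng):
        """Two-group exponential data with true log-HR 0.7."""
        n = 1500
        g = rng.integers(0, 2, n).astype(float)
        t_ev = rng.exponential(1.0 / (0.1 * np.exp(0.7 * g)))
        t = np.minimum(t_ev, 8.0)
        e = (t_ev <= 8.0).astype(int)
        fit = SurvivalData(t, e).fit_matrix(g[:, None])
        assert abs(fit.coef[0] - 0.7) < 3 * fit.se[0]

    def test_agrees_with_lifelines_with_ties(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n, p = 200, 4
        X = rng.normal(size=(n, p))
        beta = np.array([0.4, -0.3, 0.0, 0.2])
        t_ev = rng.exponential(1.0 / (0.1 * np.exp(X @ beta)))
        t = np.round(np.minimum(t_ev, rng.exponential(8, n)), 1) + 0.1  # ties
        e = rng.integers(0, 2, n) | (t_ev < 1)
        fit = SurvivalData(t, e).fit_matrix(X)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
        df["t"], df["e"] = t, e
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=2e-4)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=2e-4)
        assert abs(fit.loglik - ref.log_likelihood_) < 1e-4

    def test_score_equations_vanish_at_optimum(self, rng):
        n = 120
        X = rng.normal(size=(n, 3))
        t, e = make_survival(n, rng, lp=X @ np.array([0.5, 0.0, -0.4]))
        data = SurvivalData(t, e)
        fit = data.fit_matrix(X)
        order = np.argsort(t, kind="stable")
        _, grad, _ = _efron_lgh(np.ascontiguousarray(X[order]),
                                t[order].astype(float),
                                e[order].astype(np.int64), fit.coef, True)
        assert np.linalg.norm(grad) < 1e-6

    def test_monotone_likelihood_detected(self):
        # perfectly separating covariate diverges
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises((ConvergenceError, RankDeficiencyError)):
            SurvivalData(t, e).fit_matrix(x[:, None])

    def test_time_transform_invariance(self, rng):
        n = 100
        x = rng.normal(size=n)
        t, e = make_survival(n, rng, lp=0.5 * x)
        f1 = SurvivalData(t, e).fit_matrix(x[:, None])
        f2 = SurvivalData(np.sqrt(t), e).fit_matrix(x[:, None])  # monotone map
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)


class TestLRTest:
    def test_identical_fits_give_p_one(self, rng):
        n = 80
        x = rng.normal(size=(n, 2))
        t, e = make_survival(n, rng)
        data = SurvivalData(t, e, design=None)
        fit = data.fit_matrix(x, names=["a", "b"])
        assert lr_test(fit, fit, df=1) == 1.0

    def test_chi_square_reference_value(self):
        # statistic 3.841 on 1 df sits at the 5% point
        from tamrisk.cox import CoxFit
        f0 = CoxFit(["a"], np.zeros(1), np.eye(1), -50.0, -50.0, 10, 20)
        f1 = CoxFit(["a", "b"], np.zeros(2), np.eye(2), -50.0, -50.0 + 3.841 / 2, 10, 20)
        assert abs(lr_test(f0, f1, df=1) - 0.05) < 1e-3

    def test_inconsistent_fits_raise(self):
        from tamrisk.cox import CoxFit
        f0 = CoxFit(["a"], np.zeros(1), np.eye(1), -50.0, -48.0, 10, 20)
        f1 = CoxFit(["a", "b"], np.zeros(2), np.eye(2), -50.0, -49.0, 10, 20)
        with pytest.raises(ValueError, match="inconsistency"):
            lr_test(f0, f1, df=1)

    def test_null_rejection_rate_calibrated(self, rng):
        """Type-I error of the 1-df LR test at 0.05 under no effect."""
        R, hits = 400, 0
        for _ in range(R):
            n = 80
            x = rng.normal(size=n)
            t, e = make_survival(n, rng)
            fit = SurvivalData(t, e).fit_matrix(x[:, None])
            hits += lr_test_vs_null(fit) < 0.05
        rate = hits / R
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / R) + 1e-9


def manual_km(time, event):
    """Independent product-limit implementation for oracle comparisons."""
    s, out = 1.0, {}
    for t in sorted(set(time[event == 1])):
        n_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1 - d / n_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(2.5) == 1.0

    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [0, 1, 1, 0])
        assert np.isclose(km.survival_at(2), 2 / 3)
        assert np.isclose(km.survival_at(3), 1 / 3)

    def test_all_events_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50)
        km = km_estimate(t, np.ones(50, dtype=int))
        for q in [0.2, 0.5, 0.9]:
            tq = np.quantile(t, q)
            assert np.isclose(km.survival_at(tq), np.mean(t > tq), atol=1e-12)

    def test_matches_independent_implementation(self, rng):
        for _ in range(200):
            n = rng.integers(5, 40)
            t = np.round(rng.exponential(2, n), 1)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            km = km_estimate(t, e)
            ref = manual_km(t, e)
            for tt, ss in ref.items():
                assert np.isclose(km.survival_at(tt), ss, atol=1e-10)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 0])


def manual_logrank_2group(time, event, group):
    """Independent O-E / hypergeometric-variance log-rank computation."""
    U = V = 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n, n1 = at.sum(), (at & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return stats.chi2.sf(U * U / V, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert logrank_test(t, e, g) > 0.999

    def test_matches_hand_computed_table(self, rng):
        for _ in range(20):
            n = 30
            t = np.round(rng.exponential(2, n), 1)
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            assert np.isclose(logrank_test(t, e, g),
                              manual_logrank_2group(t, e, g), atol=1e-10)

    def test_label_permutation_invariance(self, rng):
        t = rng.exponential(2, 40)
        e = rng.integers(0, 2, 40) | 1
        g = rng.integers(0, 3, 40)
        perm = {0: 2, 1: 0, 2: 1}
        assert np.isclose(logrank_test(t, e, g),
                          logrank_test(t, e, np.vectorize(perm.get)(g)), atol=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_null_rejection_rate(self, rng):
        R, hits = 500, 0
        for _ in range(R):
            t, e = make_survival(60, rng)
            g = rng.integers(0, 2, 60)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            hits += logrank_test(t, e, g) < 0.05
        assert abs(hits / R - 0.05) < 3 * np.sqrt(0.05 * 0.95 / R) + 0.005

    def test_vectorised_scan_equals_per_cut_test(self, rng):
        """logrank_cuts must agree with the lifelines-backed test at every cut."""
        for _ in range(15):
            n = 50
            x = rng.gamma(2, 40, n)
            t, e = make_survival(n, rng)
            if e.sum() < 2:
                continue
            cuts = np.quantile(x, [0.2, 0.35, 0.5, 0.65, 0.8])
            ps = logrank_cuts(x, t, e, cuts)
            for c, p_vec in zip(cuts, ps):
                p_ref = logrank_test(t, e, (x >= c).astype(int))
                assert np.isclose(p_vec, p_ref, atol=1e-9)
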