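"""Survival-engine tests: Newton Cox fitting against independent oracles,
Wald hazard ratios, Schoenfeld diagnostics and Harrell's C."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from aldiet.cox import (
    concordance_index,
    fit_cox,
    hazard_ratios,
    log_partial_likelihood,
    schoenfeld_check,
)
from aldiet.errors import InsufficientDataError, NoEventsError, RankError


def naive_efron_loglik(beta, x, t, d):
    """Loop-based Efron partial likelihood for a single covariate;
    independent of the package's vectorised implementation."""
    beta = float(beta)
    ll = 0.0
    for tt in sorted(set(t[d == 1])):
        D = [i for i in range(len(t)) if t[i] == tt and d[i] == 1]
        R = [i for i in range(len(t)) if t[i] >= tt]
        s0 = sum(np.exp(beta * x[i]) for i in R)
        s0d = sum(np.exp(beta * x[i]) for i in D)
        for l in range(len(D)):
            ll -= np.log(s0 - (l / len(D)) * s0d)
        ll += sum(beta * x[i] for i in D)
    return ll


class TestFitCox:
    def test_matches_bruteforce_1d_oracle(self, small_survival):
        """On <=20 rows the Newton solution must agree with direct
        maximisation of an independently coded partial likelihood."""
        x, t, d = small_survival
        fit = fit_cox(x, t, d)
        res = minimize_scalar(
            lambda b: -naive_efron_loglik(b, x, t, d),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.converged
        assert abs(fit.coefficients[0] - res.x) < 1e-5
        assert abs(fit.loglik - naive_efron_loglik(fit.coefficients[0], x, t, d)) < 1e-8

    def test_matches_lifelines(self, sim_survival):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        X, t, d = sim_survival
        fit = fit_cox(X, t, d)
        df = pd.DataFrame(X, columns=list("abc"))
        df["t"], df["e"] = t, d
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.covariance)), cph.standard_errors_.values, atol=1e-5
        )

    def test_constant_covariate_rank_error(self, small_survival):
        x, t, d = small_survival
        X = np.column_stack([x, np.ones_like(x)])
        with pytest.raises(RankError):
            fit_cox(X, t, d, names=["x", "const"])

    def test_collinear_columns_named(self, sim_survival):
        X, t, d = sim_survival
        X2 = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(RankError):
            fit_cox(X2, t, d)

    def test_no_events_error(self):
        with pytest.raises(NoEventsError):
            fit_cox(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5, dtype=int))

    def test_simulation_recovers_hr2(self):
        """Two-group exponential data generated with HR 2: the replicate
        mean of fitted HRs should recover the truth."""
        rng = np.random.default_rng(10)
        hrs = []
        for _ in range(25):
            n = 600
            g = rng.integers(0, 2, n).astype(float)
            T = rng.exponential(1 / (0.15 * np.exp(np.log(2.0) * g)))
            C = rng.uniform(1, 10, n)
            t, d = np.minimum(T, C), (T <= C).astype(int)
            hrs.append(np.exp(fit_cox(g, t, d).coefficients[0]))
        mc_se = np.std(hrs, ddof=1) / np.sqrt(len(hrs))
        assert abs(np.mean(hrs) - 2.0) < 3 * mc_se

    def test_loglik_trace_monotone(self, sim_survival):
        X, t, d = sim_survival
        fit = fit_cox(X, t, d)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1.0, n)  # continuous: ties a.s. absent
        d = rng.integers(0, 2, n)
        d[0] = 1
        fe = fit_cox(X, t, d, ties_method="efron")
        fb = fit_cox(X, t, d, ties_method="breslow")
        np.testing.assert_allclose(fe.coefficients, fb.coefficients, atol=1e-9)
        assert abs(fe.loglik - fb.loglik) < 1e-9

    @pytest.mark.parametrize("shift,scale", [(5.0, 1.0), (0.0, 4.0), (-2.0, 0.25)])
    def test_affine_covariate_invariance(self, sim_survival, shift, scale):
        """Adding a constant leaves the coefficient unchanged; scaling by k
        divides it by k."""
        X, t, d = sim_survival
        fit0 = fit_cox(X, t, d)
        X2 = X.copy()
        X2[:, 0] = X2[:, 0] * scale + shift
        fit2 = fit_cox(X2, t, d)
        assert abs(fit2.coefficients[0] - fit0.coefficients[0] / scale) < 1e-6
        np.testing.assert_allclose(fit2.coefficients[1:], fit0.coefficients[1:], atol=1e-6)

    def test_covariance_symmetric_psd(self, sim_survival):
        X, t, d = sim_survival
        fit = fit_cox(X, t, d)
        np.testing.assert_allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.linalg.eigvalsh(fit.covariance) > 0)


class TestHazardRatios:
    def test_null_coefficient_hr_one(self):
        from aldiet.cox import CoxFit

        fit = CoxFit(np.zeros(1), np.array([[0.04]]), 0.0, 5, 10, "efron", True, 1)
        hr, lo, hi = hazard_ratios(fit, 0)
        assert hr == 1.0 and lo < 1.0 < hi

    def test_zero_variance_degenerate_ci(self):
        from aldiet.cox import CoxFit

        fit = CoxFit(np.array([np.log(2.0)]), np.zeros((1, 1)), 0.0, 5, 10, "efron", True, 1)
        assert hazard_ratios(fit, 0) == pytest.approx((2.0, 2.0, 2.0))

    def test_contrast_is_product_of_hrs(self, sim_survival):
        X, t, d = sim_survival
        fit = fit_cox(X, t, d)
        hr_sum, _, _ = hazard_ratios(fit, np.ones(3))
        prod = np.prod([hazard_ratios(fit, j)[0] for j in range(3)])
        assert hr_sum == pytest.approx(prod, rel=1e-12)

    def test_dimension_mismatch(self, sim_survival):
        X, t, d = sim_survival
        fit = fit_cox(X, t, d)
        with pytest.raises(ValueError):
            hazard_ratios(fit, np.ones(5))


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_mle(self, sim_survival):
        """The score equation at the MLE forces the (unscaled) residuals
        to sum to ~0 per covariate."""
        X, t, d = sim_survival
        fit = fit_cox(X, t, d)
        out = schoenfeld_check(fit, X, t, d)
        np.testing.assert_allclose(out["residuals"].sum(axis=0), 0.0, atol=1e-5)

    def test_too_few_events(self):
        x = np.arange(6.0)
        t = np.arange(1.0, 7.0)
        d = np.array([1, 1, 0, 0, 0, 0])
        fit = fit_cox(x, t, d)
        with pytest.raises(InsufficientDataError):
            schoenfeld_check(fit, x, t, d)

    def test_null_rejection_rate_near_nominal(self):
        """Under exact proportional hazards the PH test should reject at
        roughly the nominal 5% level."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_reps = 150
        for _ in range(n_reps):
            n = 120
            x = rng.normal(size=n)
            T = rng.exponential(1 / (0.2 * np.exp(0.5 * x)))
            C = rng.uniform(1, 8, n)
            t, d = np.minimum(T, C), (T <= C).astype(int)
            if d.sum() < 5:
                continue
            fit = fit_cox(x, t, d)
            out = schoenfeld_check(fit, x, t, d)
            rejections += out["p_value"][0] < 0.05
        rate = rejections / n_reps
        assert 0.01 <= rate <= 0.11  # binomial noise around 5%

    def test_power_under_time_varying_effect(self):
        """A covariate effect that switches off mid-follow-up violates PH;
        the test should reject far above the nominal rate."""
        rng = np.random.default_rng(321)
        rejections = 0
        n_reps = 40
        for _ in range(n_reps):
            n = 400
            x = rng.integers(0, 2, n).astype(float)
            # piecewise hazard: strong effect before t=1.5, none after
            lam1 = 0.5 * np.exp(1.5 * x)
            T1 = rng.exponential(1 / lam1)
            T2 = 1.5 + rng.exponential(1 / 0.5, n)
            T = np.where(T1 < 1.5, T1, T2)
            C = rng.uniform(2, 6, n)
            t, d = np.minimum(T, C), (T <= C).astype(int)
            fit = fit_cox(x, t, d)
            out = schoenfeld_check(fit, x, t, d)
            rejections += out["p_value"][0] < 0.05
        assert rejections / n_reps > 0.3


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.ones(4, dtype=int)
        risk = -t  # higher risk fails earlier
        assert concordance_index(risk, t, d) == 1.0

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(7)
        n = 3000
        t = rng.exponential(1.0, n)
        d = rng.integers(0, 2, n)
        d[:10] = 1
        risk = rng.normal(size=n)
        assert abs(concordance_index(risk, t, d) - 0.5) < 0.03

    def test_hand_fixture_exhaustive_pairs(self):
        """Five printed rows checked against explicit pair enumeration."""
        risk = np.array([0.9, 0.1, 0.5, 0.5, 0.3])
        t = np.array([1.0, 5.0, 2.0, 3.0, 4.0])
        d = np.array([1, 0, 1, 0, 1])
        conc = ties = npairs = 0
        n = 5
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if d[i] == 1 and (t[j] > t[i] or (t[j] == t[i] and d[j] == 0)):
                    npairs += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        ties += 1
        expected = (conc + 0.5 * ties) / npairs
        assert concordance_index(risk, t, d) == pytest.approx(expected)

    def test_matches_sksurv(self, sim_survival):
        sksurv = pytest.importorskip("sksurv.metrics")
        X, t, d = sim_survival
        risk = X @ np.array([0.5, -0.3, 0.1])
        mine = concordance_index(risk, t, d)
        theirs = sksurv.concordance_index_censored(d.astype(bool), t, risk)[0]
        assert mine == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs(self):
        with pytest.raises(InsufficientDataError):
            concordance_index(np.array([1.0, 2.0]), np.array([3.0, 3.0]),
                              np.array([1, 1]))


def test_log_partial_likelihood_shift_invariant(small_survival):
    """The partial likelihood only sees hazard contrasts, so the reported
    value must be invariant to recentring the covariate."""
    x, t, d = small_survival
    a = log_partial_likelihood([0.4], x, t, d)
    b = log_partial_likelihood([0.4], x + 3.0, t, d)
    assert a == pytest.approx(b, abs=1e-9)
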