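"""From-scratch Cox proportional-hazards machinery.

Implements Newton–Raphson maximisation of the Cox log partial likelihood
with Efron (default) or Breslow handling of tied event times, Wald
inference on the log-hazard scale, scaled Schoenfeld residual diagnostics
of the proportional-hazards assumption, and Harrell's concordance index.

The fitter accepts an optional quadratic penalty matrix so that the same
Newton machinery serves both ordinary Cox regression and penalised-spline
smooth terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, NoEventsError, RankError

__all__ = [
    "CoxFit",
    "fit_cox",
    "hazard_ratios",
    "schoenfeld_check",
    "concordance_index",
    "log_partial_likelihood",
]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class CoxFit:
    """Result of a (possibly penalised) Cox partial-likelihood fit.

    ``coefficients`` are log hazard ratios per design column;
    ``covariance`` is the inverse observed information (plus penalty
    curvature when a penalty was supplied), on the log-HR scale.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_events: int
    n_obs: int
    ties_method: str
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)
    names: list = field(default_factory=list)

    def summary(self) -> dict:
        se = np.sqrt(np.diag(self.covariance))
        names = self.names or [f"x{i}" for i in range(len(self.coefficients))]
        rows = []
        for j, name in enumerate(names):
            b = float(self.coefficients[j])
            rows.append(
                {
                    "term": name,
                    "coef": b,
                    "se": float(se[j]),
                    "hr": float(np.exp(b)),
                    "hr_lower95": float(np.exp(b - _Z975 * se[j])),
                    "hr_upper95": float(np.exp(b + _Z975 * se[j])),
                    "z": b / se[j] if se[j] > 0 else np.nan,
                    "p": float(2 * stats.norm.sf(abs(b / se[j]))) if se[j] > 0 else np.nan,
                }
            )
        return {
            "terms": rows,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
            "ties_method": self.ties_method,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _validate_survival(design, time, event):
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = np.asarray(time, dtype=float)
    d = np.asarray(event)
    if np.issubdtype(d.dtype, np.bool_):
        d = d.astype(int)
    d = d.astype(int)
    if X.shape[0] != t.shape[0] or t.shape[0] != d.shape[0]:
        raise ValueError("design, time and event must have equal length")
    if np.any(np.isnan(X)) or np.any(np.isnan(t)):
        raise ValueError("missing values are not allowed in the design or time")
    if not np.all((d == 0) | (d == 1)):
        raise ValueError("event indicator must be 0/1")
    if d.sum() == 0:
        raise NoEventsError("no events in the data; the partial likelihood is flat")
    return X, t, d


def _check_rank(X, names):
    """Detect constant or collinear columns via pivoted QR."""
    p = X.shape[1]
    Xc = X - X.mean(axis=0)
    scale = np.linalg.norm(Xc, axis=0)
    bad = np.where(scale < 1e-12 * max(1.0, np.abs(X).max()))[0]
    if bad.size:
        cols = [names[j] if names else int(j) for j in bad]
        raise RankError(f"constant design columns: {cols}", columns=cols)
    if p > 1:
        r = np.linalg.matrix_rank(Xc / scale, tol=1e-9)
        if r < p:
            _, R, piv = _qr_pivot(Xc / scale)
            dropped = sorted(piv[r:].tolist())
            cols = [names[j] if names else int(j) for j in dropped]
            raise RankError(f"collinear design columns: {cols}", columns=cols)


def _qr_pivot(A):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


class _PartialLikelihood:
    """Precomputed risk-set structure for fast repeated evaluation.

    Rows are sorted by follow-up time ascending.  For each distinct event
    time the suffix (risk-set) sums S0, S1 and S2 are accumulated
    incrementally from the latest event time backwards, so one evaluation
    of value/gradient/Hessian costs O(n p^2) regardless of the number of
    Newton iterations' bookkeeping.
    """

    def __init__(self, X, time, event, ties_method):
        order = np.argsort(time, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.time = time[order]
        self.event = event[order]
        self.n, self.p = self.X.shape
        self.ties_method = ties_method

        ev_idx = np.nonzero(self.event == 1)[0]
        ev_times = self.time[ev_idx]
        # distinct event times, ascending, with their tied death blocks
        self.uniq_times, inv = np.unique(ev_times, return_inverse=True)
        self.m = self.uniq_times.size
        self.death_rows = [ev_idx[inv == j] for j in range(self.m)]
        # first row index at risk for each distinct event time
        self.risk_start = np.searchsorted(self.time, self.uniq_times, side="left")

    def value_grad_hess(self, beta, need_hess=True):
        X, time, event = self.X, self.time, self.event
        n, p = self.n, self.p
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
        w = np.exp(eta)
        wX = w[:, None] * X

        loglik = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p)) if need_hess else None

        # accumulate risk-set sums from the last event time backwards
        S0 = 0.0
        S1 = np.zeros(p)
        S2 = np.zeros((p, p)) if need_hess else None
        hi = n  # rows [risk_start[j], hi) not yet absorbed
        for j in range(self.m - 1, -1, -1):
            lo = self.risk_start[j]
            if hi > lo:
                blk = slice(lo, hi)
                S0 += w[blk].sum()
                S1 += wX[blk].sum(axis=0)
                if need_hess:
                    S2 += X[blk].T @ wX[blk]
                hi = lo
            rows = self.death_rows[j]
            d = rows.size
            loglik += eta[rows].sum()
            grad += X[rows].sum(axis=0)
            if self.ties_method == "breslow" or d == 1:
                M0 = np.full(d, S0)
                M1 = np.tile(S1, (d, 1))
            else:
                s0 = w[rows].sum()
                s1 = wX[rows].sum(axis=0)
                frac = np.arange(d) / d
                M0 = S0 - frac * s0
                M1 = S1[None, :] - frac[:, None] * s1[None, :]
            loglik -= np.log(M0).sum()
            mu = M1 / M0[:, None]
            grad -= mu.sum(axis=0)
            if need_hess:
                if self.ties_method == "breslow" or d == 1:
                    hess += d * (S2 / S0 - np.outer(S1 / S0, S1 / S0))
                else:
                    s2 = X[rows].T @ wX[rows]
                    for l in range(d):
                        Ml2 = S2 - (l / d) * s2
                        hess += Ml2 / M0[l] - np.outer(mu[l], mu[l])
        return loglik, grad, hess


def log_partial_likelihood(beta, design, time, event, ties_method="efron"):
    """Log partial likelihood at ``beta`` (no fitting); used by oracles."""
    X, t, d = _validate_survival(design, time, event)
    pl = _PartialLikelihood(X, t, d, ties_method)
    ll, _, _ = pl.value_grad_hess(np.asarray(beta, dtype=float), need_hess=False)
    return float(ll)


def fit_cox(
    design,
    time,
    event,
    ties_method: str = "efron",
    names=None,
    penalty=None,
    init=None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
    check_rank: bool = True,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    design : (n, p) array
        Numeric covariate matrix (no intercept; the baseline hazard absorbs it).
    time, event : (n,) arrays
        Follow-up time (years) and 0/1 event indicator.
    ties_method : {"efron", "breslow"}
        Correction for tied event times. Efron is the default.
    penalty : (p, p) array, optional
        Quadratic penalty matrix P; the objective becomes
        ``loglik(beta) - 0.5 * beta' P beta`` (used by the P-spline fitter).

    Newton steps are halved whenever the (penalised) objective would
    decrease, guaranteeing monotone ascent. Convergence is declared when
    the maximum absolute (penalised) score drops below ``score_tol`` or
    the relative objective change falls below ``loglik_tol``.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties_method {ties_method!r}")
    X, t, d = _validate_survival(design, time, event)
    names = list(names) if names is not None else []
    if check_rank and penalty is None:
        _check_rank(X, names)
    p = X.shape[1]
    P = None if penalty is None else np.asarray(penalty, dtype=float)

    pl = _PartialLikelihood(X, t, d, ties_method)
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    def objective(ll, b):
        return ll if P is None else ll - 0.5 * b @ P @ b

    ll, g, H = pl.value_grad_hess(beta)
    if P is not None:
        g = g - P @ beta
        H = H + P
    obj = objective(ll, beta)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"singular information matrix: {exc}") from exc
        # step halving: insist on monotone ascent of the objective
        alpha = 1.0
        for _ in range(40):
            beta_new = beta + alpha * step
            ll_new, g_new, H_new = pl.value_grad_hess(beta_new)
            if P is not None:
                obj_new = objective(ll_new, beta_new)
                g_new = g_new - P @ beta_new
                H_new = H_new + P
            else:
                obj_new = ll_new
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12 * max(1.0, abs(obj)):
                break
            alpha *= 0.5
        else:
            break  # cannot make ascent progress
        rel_change = abs(obj_new - obj) / max(1.0, abs(obj))
        beta, obj, g, H = beta_new, obj_new, g_new, H_new
        trace.append(obj)
        if np.max(np.abs(g)) < score_tol or rel_change < loglik_tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"singular information at the optimum: {exc}") from exc
    cov = (cov + cov.T) / 2
    ll_final, _, _ = pl.value_grad_hess(beta, need_hess=False)
    return CoxFit(
        coefficients=beta,
        covariance=cov,
        loglik=float(ll_final),
        n_events=int(d.sum()),
        n_obs=int(len(t)),
        ties_method=ties_method,
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
        names=names,
    )


def hazard_ratios(fit: CoxFit, contrast):
    """Hazard ratio and Wald 95% CI for a coefficient or linear combination.

    ``contrast`` may be an integer index or a length-p vector c, giving
    HR = exp(c'beta) with CI exp(c'beta +/- 1.96 sqrt(c' Sigma c)).
    """
    p = len(fit.coefficients)
    if np.isscalar(contrast) and not isinstance(contrast, (np.ndarray,)):
        c = np.zeros(p)
        c[int(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)
        if c.shape != (p,):
            raise ValueError(f"contrast must have length {p}, got shape {c.shape}")
    est = float(c @ fit.coefficients)
    se = float(np.sqrt(c @ fit.covariance @ c))
    return np.exp(est), np.exp(est - _Z975 * se), np.exp(est + _Z975 * se)


def schoenfeld_check(fit: CoxFit, design, time, event):
    """Scaled Schoenfeld residuals and a correlation-with-time PH test.

    At each event time the (unscaled) residual is the covariate vector of
    the failing subject minus the risk-set weighted mean. Scaling follows
    Grambsch & Therneau: r* = d * Cov(beta) @ r + beta. The test statistic
    per covariate is the Pearson correlation between the scaled residual
    and follow-up time, with a t-distribution p-value on d - 2 df.
    """
    X, t, d = _validate_survival(design, time, event)
    if d.sum() < 3:
        raise InsufficientDataError("need at least 3 events for Schoenfeld diagnostics")
    beta = fit.coefficients
    pl = _PartialLikelihood(X, t, d, fit.ties_method)
    eta = pl.X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * pl.X

    res_times = []
    residuals = []
    S0, S1 = 0.0, np.zeros(pl.p)
    hi = pl.n
    for j in range(pl.m - 1, -1, -1):
        lo = pl.risk_start[j]
        if hi > lo:
            blk = slice(lo, hi)
            S0 += w[blk].sum()
            S1 += wX[blk].sum(axis=0)
            hi = lo
        xbar = S1 / S0
        for i in pl.death_rows[j]:
            res_times.append(pl.time[i])
            residuals.append(pl.X[i] - xbar)
    res_times = np.asarray(res_times[::-1])
    residuals = np.asarray(residuals[::-1])

    n_ev = residuals.shape[0]
    scaled = n_ev * residuals @ fit.covariance + beta[None, :]
    pvals = np.empty(pl.p)
    corrs = np.empty(pl.p)
    for k in range(pl.p):
        r = np.corrcoef(res_times, scaled[:, k])[0, 1]
        if not np.isfinite(r):
            corrs[k], pvals[k] = 0.0, 1.0
            continue
        r = np.clip(r, -0.999999999, 0.999999999)
        tstat = r * np.sqrt((n_ev - 2) / (1 - r * r))
        corrs[k] = r
        pvals[k] = 2 * stats.t.sf(abs(tstat), df=n_ev - 2)
    return {
        "event_times": res_times,
        "residuals": residuals,
        "scaled_residuals": scaled,
        "correlation": corrs,
        "p_value": pvals,
    }


def concordance_index(risk_score, time, event):
    """Harrell's C-index for right-censored data.

    Comparable pairs are those orderable under censoring: the member with
    the shorter follow-up experienced the event (pairs tied on time with
    both events are not comparable). Concordant pairs have higher risk for
    the earlier failure; risk ties count 0.5.
    """
    r = np.asarray(risk_score, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    ev = np.nonzero(d == 1)[0]
    conc = 0.0
    ties = 0.0
    npairs = 0
    for i in ev:
        later = (t > t[i]) | ((t == t[i]) & (d == 0))
        npairs += int(later.sum())
        conc += float((r[later] < r[i]).sum())
        ties += float((r[later] == r[i]).sum())
    if npairs == 0:
        raise InsufficientDataError("no comparable pairs; C-index undefined")
    return (conc + 0.5 * ties) / npairs
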