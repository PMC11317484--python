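"""Penalised cubic-spline (P-spline) Cox dose-response for the diet score.

The score enters through a cubic B-spline basis on the truncated
[5th, 95th] percentile range with a second-order difference penalty on
adjacent basis coefficients, so the fit shrinks toward log-linearity as
the penalty grows and is robust to knot placement. Covariates enter
unpenalised. The penalty weight is chosen by AIC (with effective degrees
of freedom tr((H + lambda*P)^-1 H)) over a log-spaced grid unless given.

Because the Cox partial likelihood absorbs constants, the first basis
column is dropped (the basis is a partition of unity, so its span less
constants is unchanged); hazard-ratio curves are normalised to a stated
reference score, HR(reference) = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import chi2

from .cox import CoxFit, fit_cox
from .errors import InsufficientDataError, NoEventsError

__all__ = [
    "SplineCurve",
    "truncate_range",
    "spline_basis",
    "fit_spline_cox",
    "hr_curve",
    "stratified_curves",
    "nonlinearity_test",
]

_Z975 = 1.959963984540054


@dataclass
class SplineCurve:
    grid: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference_value: float
    basis_meta: dict = field(default_factory=dict)
    low_power: bool = False

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "score": self.grid,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def truncate_range(scores, lower_pct: float = 5.0, upper_pct: float = 95.0):
    """Empirical truncation bounds (linear-interpolation percentiles)."""
    s = np.asarray(scores, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 20:
        raise InsufficientDataError("need >= 20 non-missing scores to truncate")
    lo, hi = np.percentile(s, [lower_pct, upper_pct])
    return float(lo), float(hi)


def spline_basis(x, low: float, high: float, basis_size: int = 10, degree: int = 3):
    """Uniform (Eilers-Marx) cubic B-spline design matrix on [low, high].

    Equally spaced knots extend ``degree`` segments beyond the range so
    every basis function is a shifted copy of the same kernel; a
    difference penalty on the coefficients then leaves polynomials of
    matching order unpenalised exactly. Values outside the range are
    clipped (truncation). Returns ``(matrix, knots)``.
    """
    if basis_size < 4:
        raise ValueError("basis_size must be >= 4")
    if not high > low:
        raise ValueError("degenerate truncation range (low == high)")
    n_seg = basis_size - degree
    h = (high - low) / n_seg
    knots = low + h * np.arange(-degree, n_seg + degree + 1)
    xc = np.clip(np.asarray(x, dtype=float), low, high)
    # keep strictly inside the valid evaluation interval at the right edge
    xc = np.minimum(xc, high - 1e-12 * max(1.0, abs(high)))
    B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return B, knots


def _second_difference_penalty(basis_size: int):
    D = np.diff(np.eye(basis_size), n=2, axis=0)
    return D.T @ D


def fit_spline_cox(
    score,
    time,
    event,
    covariate_design=None,
    basis_size: int = 10,
    penalty_weight="auto",
    n_weights: int = 30,
    weight_range=(1e-2, 1e5),
    trunc=None,
    covariate_names=None,
):
    """Penalised-spline Cox fit of the score effect.

    Returns ``(CoxFit, basis_meta)``. ``basis_meta`` records the knots,
    truncation range, chosen penalty weight, effective df, and which
    design columns belong to the spline (the first basis column is
    dropped for identifiability; its coefficient is fixed at zero).
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    if d.sum() == 0:
        raise NoEventsError("no events")
    lo, hi = truncate_range(s) if trunc is None else trunc
    B, knots = spline_basis(s, lo, hi, basis_size)
    Bs = B[:, 1:]  # drop first column; constants are absorbed by the baseline
    if covariate_design is not None:
        Z = np.asarray(covariate_design, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        X = np.hstack([Bs, Z])
    else:
        Z = None
        X = Bs
    p_spline = Bs.shape[1]
    p_total = X.shape[1]
    P_full = _second_difference_penalty(basis_size)[1:, 1:]

    def penalty_matrix(lam):
        P = np.zeros((p_total, p_total))
        P[:p_spline, :p_spline] = lam * P_full
        return P

    def fit_at(lam, init=None):
        return fit_cox(
            X, t, d, penalty=penalty_matrix(lam), init=init, check_rank=False
        )

    if penalty_weight == "auto":
        grid = np.geomspace(weight_range[0], weight_range[1], n_weights)
        best = None
        init = None
        for lam in grid[::-1]:  # heavy smoothing first: stable warm starts
            fit = fit_at(lam, init=init)
            init = fit.coefficients
            edf = _effective_df(fit, penalty_matrix(lam))
            aic = -2.0 * fit.loglik + 2.0 * edf
            if best is None or aic < best[0]:
                best = (aic, lam, fit, edf)
        _, lam, fit, edf = best
    else:
        lam = float(penalty_weight)
        fit = fit_at(lam)
        edf = _effective_df(fit, penalty_matrix(lam))

    meta = {
        "knots": knots,
        "degree": 3,
        "basis_size": basis_size,
        "trunc_low": lo,
        "trunc_high": hi,
        "penalty_weight": lam,
        "effective_df": edf,
        "spline_columns": list(range(p_spline)),
        "dropped_first_column": True,
        "covariate_names": list(covariate_names) if covariate_names else [],
    }
    return fit, meta


def _effective_df(fit: CoxFit, P):
    """tr((H + P)^-1 H) with H recovered from the penalised covariance."""
    Vinv = np.linalg.inv(fit.covariance)  # = H + P at the optimum
    H = Vinv - P
    return float(np.trace(fit.covariance @ H))


def hr_curve(fit: CoxFit, basis_meta: dict, reference: float = None,
             n_grid: int = 100) -> SplineCurve:
    """Hazard-ratio curve vs a reference score with pointwise Wald bands.

    HR(x) = exp(s(x) - s(ref)); the variance of the log contrast uses the
    spline block of the penalised covariance. The reference defaults to
    the lower truncation bound (the lowest in-range score).
    """
    lo, hi = basis_meta["trunc_low"], basis_meta["trunc_high"]
    if reference is None:
        reference = lo
    if not lo <= reference <= hi:
        raise ValueError("reference outside the truncated range")
    grid = np.linspace(lo, hi, n_grid)
    Bg, _ = spline_basis(grid, lo, hi, basis_meta["basis_size"])
    Br, _ = spline_basis(np.array([reference]), lo, hi, basis_meta["basis_size"])
    cols = basis_meta["spline_columns"]
    Cg = Bg[:, 1:] - Br[:, 1:]  # contrast in the reduced basis
    beta_s = fit.coefficients[cols]
    V = fit.covariance[np.ix_(cols, cols)]
    log_hr = Cg @ beta_s
    var = np.einsum("ij,jk,ik->i", Cg, V, Cg)
    se = np.sqrt(np.maximum(var, 0.0))
    return SplineCurve(
        grid=grid,
        hr=np.exp(log_hr),
        ci_lower=np.exp(log_hr - _Z975 * se),
        ci_upper=np.exp(log_hr + _Z975 * se),
        reference_value=float(reference),
        basis_meta=basis_meta,
    )


def stratified_curves(
    score,
    strata,
    time,
    event,
    covariate_design=None,
    basis_size: int = 10,
    reference: float = None,
    **kwargs,
):
    """Independent spline fits per stratum on a common truncated range.

    ``strata`` holds labels (e.g. alcohol <=14 vs >14 units/week). Strata
    with fewer than 10 events are returned flagged ``low_power``; strata
    with no events raise.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    g = np.asarray(strata)
    trunc = truncate_range(s)
    out = {}
    for label in np.unique(g):
        mask = g == label
        if d[mask].sum() == 0:
            raise NoEventsError(f"stratum {label!r} has no events")
        Z = None
        if covariate_design is not None:
            Z = np.asarray(covariate_design, dtype=float)
            Z = Z[mask] if Z.ndim == 1 else Z[mask, :]
        fit, meta = fit_spline_cox(
            s[mask], t[mask], d[mask], covariate_design=Z,
            basis_size=basis_size, trunc=trunc, **kwargs,
        )
        curve = hr_curve(fit, meta, reference=reference)
        curve.low_power = int(d[mask].sum()) < 10
        out[label] = curve
    return out


def nonlinearity_test(score, time, event, covariate_design=None, **kwargs):
    """Likelihood-ratio comparison of the spline fit against a linear
    score term; the df is the spline's effective df minus one."""
    s = np.asarray(score, dtype=float)
    fit_s, meta = fit_spline_cox(s, time, event, covariate_design, **kwargs)
    # the linear comparator sees the same truncated exposure as the spline
    s_lin = np.clip(s, meta["trunc_low"], meta["trunc_high"])
    if covariate_design is not None:
        Z = np.asarray(covariate_design, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        X_lin = np.hstack([s_lin[:, None], Z])
    else:
        X_lin = s_lin[:, None]
    fit_l = fit_cox(X_lin, time, event)
    stat = 2.0 * (fit_s.loglik - fit_l.loglik)
    df = max(meta["effective_df"] - 1.0, 0.5)
    return {
        "lr_statistic": float(stat),
        "df": df,
        "p_value": float(chi2.sf(max(stat, 0.0), df)),
        "spline_loglik": fit_s.loglik,
        "linear_loglik": fit_l.loglik,
    }
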