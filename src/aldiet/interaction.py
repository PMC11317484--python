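"""Additive and multiplicative interaction statistics and population
attributable fractions from Cox model fits.

The relative excess risk due to interaction (RERI) for a 2x2 joint
exposure with doubly-unexposed reference is

    RERI = HR11 - HR10 - HR01 + 1,

zero under exact additivity of excess risks. Its confidence interval
comes from the multivariate delta method on the dummy-coefficient
covariance block, with a percentile bootstrap-of-coefficients fallback.
The multiplicative interaction ratio is HR11 / (HR10 * HR01), a linear
contrast on the log scale.

Attributable fractions implement Levin's formula over exposure
categories (reference HR = 1) and a case-weighted variant when case
counts per category are available; interval estimates resample the
coefficients from the fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import CoxFit

__all__ = [
    "InteractionResult",
    "PAFResult",
    "reri_from_fit",
    "multiplicative_interaction",
    "paf",
    "continuous_exposure_interaction",
    "reri_point",
]

_Z975 = 1.959963984540054


@dataclass
class InteractionResult:
    cell_HRs: dict
    reri: float
    reri_ci: tuple
    mult_ratio: float
    mult_ci: tuple
    scale_note: str = ""

    def to_dict(self):
        return {
            "cell_HRs": self.cell_HRs,
            "reri": self.reri,
            "reri_ci": list(self.reri_ci),
            "mult_ratio": self.mult_ratio,
            "mult_ci": list(self.mult_ci),
            "scale_note": self.scale_note,
        }


@dataclass
class PAFResult:
    exposure: str
    prevalences: list
    hazard_ratios: list
    paf: float
    paf_ci: tuple
    method: str

    def to_dict(self):
        return {
            "exposure": self.exposure,
            "prevalences": list(self.prevalences),
            "hazard_ratios": list(self.hazard_ratios),
            "paf": self.paf,
            "paf_ci": list(self.paf_ci),
            "method": self.method,
        }


def reri_point(hr10: float, hr01: float, hr11: float) -> float:
    """RERI from three cell hazard ratios (reference cell HR = 1)."""
    return hr11 - hr10 - hr01 + 1.0


def _check_indices(fit, idx10, idx01, idx11):
    p = len(fit.coefficients)
    idx = (idx10, idx01, idx11)
    if len(set(idx)) != 3:
        raise ValueError("cell coefficient indices must be distinct")
    for i in idx:
        if not 0 <= i < p:
            raise ValueError(f"coefficient index {i} out of range for p={p}")
    return idx


def reri_from_fit(fit: CoxFit, idx10: int, idx01: int, idx11: int,
                  method: str = "delta", n_boot: int = 10_000, seed: int = 0):
    """RERI with 95% CI from joint-category dummy coefficients.

    ``idx10``/``idx01``/``idx11`` address the singly- and doubly-exposed
    dummies (reference = doubly unexposed). The delta-method variance
    uses gradient ``(-e^b10, -e^b01, e^b11)`` against the 3x3 covariance
    block; ``method="bootstrap"`` resamples coefficients from the fit's
    Gaussian approximation and takes percentile limits.
    """
    idx10, idx01, idx11 = _check_indices(fit, idx10, idx01, idx11)
    b = fit.coefficients
    V = fit.covariance
    h10, h01, h11 = np.exp(b[idx10]), np.exp(b[idx01]), np.exp(b[idx11])
    est = reri_point(h10, h01, h11)
    sel = [idx10, idx01, idx11]
    Vblk = V[np.ix_(sel, sel)]
    if method == "delta":
        grad = np.array([-h10, -h01, h11])
        var = float(grad @ Vblk @ grad)
        se = np.sqrt(max(var, 0.0))
        ci = (est - _Z975 * se, est + _Z975 * se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(b[sel], Vblk, size=n_boot)
        vals = np.exp(draws[:, 2]) - np.exp(draws[:, 0]) - np.exp(draws[:, 1]) + 1
        ci = tuple(np.percentile(vals, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return est, ci


def multiplicative_interaction(fit: CoxFit, idx10: int, idx01: int, idx11: int):
    """Ratio e^(b11 - b10 - b01) with a log-scale delta (Wald) CI."""
    idx10, idx01, idx11 = _check_indices(fit, idx10, idx01, idx11)
    p = len(fit.coefficients)
    c = np.zeros(p)
    c[idx11] = 1.0
    c[idx10] = -1.0
    c[idx01] = -1.0
    est = float(c @ fit.coefficients)
    se = float(np.sqrt(c @ fit.covariance @ c))
    return np.exp(est), (np.exp(est - _Z975 * se), np.exp(est + _Z975 * se))


def interaction_from_fit(fit: CoxFit, idx10: int, idx01: int, idx11: int,
                         scale_note: str = "") -> InteractionResult:
    """Bundle cell HRs, RERI and the multiplicative ratio for reporting."""
    from .cox import hazard_ratios

    cells = {}
    for name, idx in (("10", idx10), ("01", idx01), ("11", idx11)):
        hr, lo, hi = hazard_ratios(fit, idx)
        cells[name] = {"hr": hr, "lower95": lo, "upper95": hi}
    reri, reri_ci = reri_from_fit(fit, idx10, idx01, idx11)
    mult, mult_ci = multiplicative_interaction(fit, idx10, idx01, idx11)
    return InteractionResult(
        cell_HRs=cells,
        reri=reri,
        reri_ci=reri_ci,
        mult_ratio=mult,
        mult_ci=mult_ci,
        scale_note=scale_note,
    )


def _levin(prev_exposed, hrs_exposed):
    excess = np.sum(prev_exposed * (hrs_exposed - 1.0))
    return excess / (1.0 + excess)


def paf(
    category_prevalences,
    category_HRs,
    case_counts=None,
    method: str = "levin",
    fit: CoxFit = None,
    hr_indices=None,
    n_draws: int = 10_000,
    seed: int = 0,
    exposure: str = "",
) -> PAFResult:
    """Population attributable fraction over exposure categories.

    ``category_prevalences`` include the reference category (HR = 1) and
    must sum to 1. Levin's formula uses prevalences and HRs; the
    case-weighted variant uses the case distribution:
    ``sum_c (cases_c / cases) * (HR_c - 1) / HR_c``.

    When ``fit`` and ``hr_indices`` (coefficient index per non-reference
    category) are given, a Monte-Carlo percentile CI is produced by
    resampling coefficients from the fit covariance; otherwise the CI is
    degenerate at the estimate.
    """
    prev = np.asarray(category_prevalences, dtype=float)
    hrs = np.asarray(category_HRs, dtype=float)
    if prev.shape != hrs.shape:
        raise ValueError("prevalences and HRs must align")
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError(f"prevalences sum to {prev.sum()!r}, not 1")
    if abs(hrs[0] - 1.0) > 1e-12:
        raise ValueError("first category is the reference and must have HR = 1")

    def point(h):
        if method == "levin":
            return _levin(prev[1:], h[1:])
        if method == "case_weighted":
            if case_counts is None:
                raise ValueError("case_weighted PAF needs case counts per category")
            cc = np.asarray(case_counts, dtype=float)
            return float(np.sum((cc / cc.sum()) * (h - 1.0) / h))
        raise ValueError(f"unknown PAF method {method!r}")

    est = float(point(hrs))
    if fit is not None and hr_indices is not None:
        sel = list(hr_indices)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            fit.coefficients[sel], fit.covariance[np.ix_(sel, sel)], size=n_draws
        )
        vals = np.empty(n_draws)
        for i in range(n_draws):
            h = np.concatenate([[1.0], np.exp(draws[i])])
            vals[i] = point(h)
        ci = tuple(np.percentile(vals, [2.5, 97.5]))
    else:
        ci = (est, est)
    return PAFResult(
        exposure=exposure,
        prevalences=prev.tolist(),
        hazard_ratios=hrs.tolist(),
        paf=est,
        paf_ci=ci,
        method=method,
    )


def continuous_exposure_interaction(
    fit: CoxFit,
    score_idx: int,
    alcohol_idx: int,
    product_idx: int,
    score_contrast: float = 1.0,
    alcohol_contrast: float = 1.0,
):
    """RERI at a stated contrast for a continuous-by-continuous model.

    The model holds a continuous diet score, weekly alcohol scaled per 7
    units, and their product. The implied 2x2 cell log hazards at
    ``(+score_contrast, +alcohol_contrast)`` versus zero feed the same
    delta-method RERI machinery:

        a = b_s * s,  b = b_a * u,  ab = a + b + b_sa * s * u.
    """
    p = len(fit.coefficients)
    for i in (score_idx, alcohol_idx, product_idx):
        if not 0 <= i < p:
            raise ValueError(f"coefficient index {i} out of range")
    if len({score_idx, alcohol_idx, product_idx}) != 3:
        raise ValueError("indices must be distinct")
    b = fit.coefficients
    V = fit.covariance
    s, u = float(score_contrast), float(alcohol_contrast)
    c10 = np.zeros(p); c10[score_idx] = s
    c01 = np.zeros(p); c01[alcohol_idx] = u
    c11 = c10 + c01
    c11[product_idx] = s * u
    a10, a01, a11 = (float(c @ b) for c in (c10, c01, c11))
    est = np.exp(a11) - np.exp(a10) - np.exp(a01) + 1.0
    grad = -np.exp(a10) * c10 - np.exp(a01) * c01 + np.exp(a11) * c11
    var = float(grad @ V @ grad)
    se = np.sqrt(max(var, 0.0))
    return float(est), (est - _Z975 * se, est + _Z975 * se)
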