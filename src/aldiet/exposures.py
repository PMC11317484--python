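"""Analysis-variable derivation: alcohol risk bands, metabolic-syndrome
flags, joint diet-by-alcohol categories, exclusion filters and
descriptive statistics.

Alcohol banding follows UK guidance with sex-specific upper bands:
lower risk <=14 units/week for both sexes; increasing risk 15-34 units
for women and 15-49 for men; higher risk >=35 for women and >=50 for
men. Non-integer unit totals between the worded bands resolve as
lower <= 14 < increasing, so 14.5 units is increasing risk.

Metabolic syndrome components use the harmonised clinical thresholds:
waist circumference strictly greater than 88 cm (women) / 102 cm (men);
fasting glucose >= 5.6 mmol/l or physician-diagnosed diabetes; systolic
BP >= 130 and/or diastolic BP >= 85 mm Hg or diagnosed hypertension;
triglycerides >= 1.7 mmol/l; HDL cholesterol < 1.3 mmol/l (women) /
< 1.0 mmol/l (men).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError

__all__ = [
    "ALCOHOL_LEVELS",
    "JOINT_LABELS",
    "categorize_alcohol",
    "metabolic_flags",
    "joint_category",
    "apply_exclusions",
    "descriptives",
    "cohens_d",
    "phi_coefficient",
    "ExclusionLog",
]

ALCOHOL_LEVELS = ["lower", "increasing", "higher"]

#: the six joint diet-by-alcohol categories; category 1 is the referent
JOINT_LABELS = [
    "lower_diet_lower_alcohol",
    "lower_diet_increasing_alcohol",
    "lower_diet_higher_alcohol",
    "higher_diet_lower_alcohol",
    "higher_diet_increasing_alcohol",
    "higher_diet_higher_alcohol",
]


def categorize_alcohol(units, sex):
    """Sex-specific alcohol risk band from weekly units.

    Vectorised; ``sex`` holds ``"woman"``/``"man"`` labels. Negative unit
    values raise.
    """
    u = np.asarray(units, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    s = np.atleast_1d(np.asarray(sex, dtype=object))
    if s.size == 1 and u.size > 1:
        s = np.repeat(s, u.size)
    if np.any(u[~np.isnan(u)] < 0):
        raise ValueError("alcohol units must be >= 0")
    woman = s == "woman"
    higher_cut = np.where(woman, 35.0, 50.0)
    out = np.where(
        np.isnan(u),
        None,
        np.where(u >= higher_cut, "higher", np.where(u > 14.0, "increasing", "lower")),
    )
    return out.item() if scalar else out


def metabolic_flags(
    waist_cm,
    glucose_mmol_l,
    sbp_mmhg,
    dbp_mmhg,
    tg_mmol_l,
    hdl_mmol_l,
    diabetes_dx,
    htn_dx,
    sex,
):
    """The five metabolic-syndrome component flags.

    Physician-diagnosis flags override the measured thresholds for
    hyperglycaemia/diabetes and hypertension. Missing measurements
    propagate as missing flags (NaN) unless a diagnosis decides the flag.

    Returns a DataFrame with columns ``central_obesity``,
    ``hyperglycaemia``, ``hypertension``, ``high_tg``, ``low_hdl``
    (floats 0/1/NaN).
    """
    waist = np.atleast_1d(np.asarray(waist_cm, dtype=float))
    glu = np.atleast_1d(np.asarray(glucose_mmol_l, dtype=float))
    sbp = np.atleast_1d(np.asarray(sbp_mmhg, dtype=float))
    dbp = np.atleast_1d(np.asarray(dbp_mmhg, dtype=float))
    tg = np.atleast_1d(np.asarray(tg_mmol_l, dtype=float))
    hdl = np.atleast_1d(np.asarray(hdl_mmol_l, dtype=float))
    ddx = np.atleast_1d(np.asarray(diabetes_dx)).astype(bool)
    hdx = np.atleast_1d(np.asarray(htn_dx)).astype(bool)
    s = np.atleast_1d(np.asarray(sex, dtype=object))
    woman = s == "woman"

    def _thresh(values, flag):
        return np.where(np.isnan(values), np.nan, flag.astype(float))

    waist_cut = np.where(woman, 88.0, 102.0)
    central = _thresh(waist, waist > waist_cut)  # strict >

    hyper = _thresh(glu, glu >= 5.6)
    hyper = np.where(ddx, 1.0, hyper)  # diagnosis overrides

    # "and/or": any non-missing measurement at threshold decides high;
    # both present and below decides low; otherwise unknown
    bp_known_high = (np.nan_to_num(sbp, nan=-np.inf) >= 130.0) | (
        np.nan_to_num(dbp, nan=-np.inf) >= 85.0
    )
    bp_known_low = (~np.isnan(sbp)) & (~np.isnan(dbp)) & (sbp < 130.0) & (dbp < 85.0)
    htn = np.where(bp_known_high, 1.0, np.where(bp_known_low, 0.0, np.nan))
    htn = np.where(hdx, 1.0, htn)

    high_tg = _thresh(tg, tg >= 1.7)
    hdl_cut = np.where(woman, 1.3, 1.0)
    low_hdl = _thresh(hdl, hdl < hdl_cut)

    return pd.DataFrame(
        {
            "central_obesity": central,
            "hyperglycaemia": hyper,
            "hypertension": htn,
            "high_tg": high_tg,
            "low_hdl": low_hdl,
        }
    )


def joint_category(diet_binary, alcohol_cat):
    """Joint exposure label from the median-split diet indicator and the
    alcohol risk band. Category 1 (lower diet, lower alcohol) is the
    referent."""
    d = np.atleast_1d(np.asarray(diet_binary, dtype=float))
    a = np.atleast_1d(np.asarray(alcohol_cat, dtype=object))
    scalar = np.isscalar(diet_binary) or (
        not hasattr(diet_binary, "__len__") and d.size == 1
    )
    out = np.full(d.shape, None, dtype=object)
    for i in range(d.size):
        if np.isnan(d[i]) or a[i] is None:
            continue
        if a[i] not in ALCOHOL_LEVELS:
            raise ValueError(f"invalid alcohol category {a[i]!r}")
        idx = int(d[i]) * 3 + ALCOHOL_LEVELS.index(a[i])
        out[i] = JOINT_LABELS[idx]
    return out.item() if scalar else out


@dataclass
class ExclusionLog:
    """Row counts removed per rule, in application order."""

    n_input: int = 0
    baseline_condition: int = 0
    missing_diet: int = 0
    missing_covariates: int = 0
    landmark_events: int = 0
    n_retained: int = 0

    def validate(self):
        removed = (
            self.baseline_condition
            + self.missing_diet
            + self.missing_covariates
            + self.landmark_events
        )
        if removed != self.n_input - self.n_retained:
            raise AssertionError("exclusion counts do not partition removed rows")
        return self

    def to_dict(self) -> dict:
        return dict(self.__dict__)


#: covariates whose missingness triggers complete-case exclusion
DEFAULT_COVARIATE_COLUMNS = [
    "age",
    "sex",
    "deprivation",
    "ethnicity",
    "smoking",
    "physical_activity",
    "alcohol_units",
    "alcohol_frequency",
    "waist_cm",
    "glucose_mmol_l",
    "sbp_mmhg",
    "dbp_mmhg",
    "tg_mmol_l",
    "hdl_mmol_l",
]


def apply_exclusions(
    cohort: pd.DataFrame,
    diet_columns,
    covariate_columns=None,
    landmark_years: float = 2.0,
):
    """Apply the analysis filters, in order, logging removed counts.

    1. baseline liver-disease/drug-disorder flag;
    2. missing any selected diet item;
    3. missing any covariate;
    4. landmark rule: event within ``landmark_years`` of baseline
       (early-censored participants are retained).

    Returns ``(filtered_cohort, ExclusionLog)``.
    """
    cov_cols = (
        [c for c in DEFAULT_COVARIATE_COLUMNS if c in cohort.columns]
        if covariate_columns is None
        else list(covariate_columns)
    )
    missing_cols = [c for c in list(diet_columns) + cov_cols if c not in cohort.columns]
    if missing_cols:
        raise SchemaError(f"cohort lacks columns: {missing_cols}")

    log = ExclusionLog(n_input=len(cohort))
    df = cohort

    flag = df["baseline_exclusion_flag"].fillna(False).astype(bool)
    log.baseline_condition = int(flag.sum())
    df = df[~flag]

    miss_diet = df[list(diet_columns)].isna().any(axis=1)
    log.missing_diet = int(miss_diet.sum())
    df = df[~miss_diet]

    miss_cov = df[cov_cols].isna().any(axis=1)
    log.missing_covariates = int(miss_cov.sum())
    df = df[~miss_cov]

    early_event = (df["event"] == 1) & (df["followup_years"] < landmark_years)
    log.landmark_events = int(early_event.sum())
    df = df[~early_event]

    log.n_retained = len(df)
    return df.copy(), log.validate()


def cohens_d(x1, x2):
    """Standardised mean difference with pooled SD."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise InsufficientDataError("each group needs n >= 2 for Cohen's d")
    n1, n2 = len(x1), len(x2)
    pooled = np.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return float((x1.mean() - x2.mean()) / pooled)


def phi_coefficient(table_2x2):
    """Phi = sqrt(chi-square / n) for a 2x2 contingency table, signed by
    the association direction (ad - bc)."""
    T = np.asarray(table_2x2, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("phi_coefficient expects a 2x2 table")
    a, b = T[0]
    c, d = T[1]
    n = T.sum()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return float((a * d - b * c) / np.sqrt(denom))


def descriptives(
    cohort: pd.DataFrame,
    group_col: str,
    continuous=("age", "deprivation", "alcohol_units"),
    categorical=("sex", "ethnicity", "smoking", "physical_activity", "alcohol_frequency"),
    diet_group_col=None,
    frequency_band_levels=("three_four_week", "daily"),
):
    """Per-group summary table plus the two between-diet-group effect sizes.

    Continuous variables are reported as mean (SD); categorical as n (%).
    When ``diet_group_col`` is given, Cohen's d contrasts alcohol units
    between the two diet-score groups and the Phi coefficient is computed
    on the 2x2 diet-group by drinking-frequency-band table, where the
    band dichotomises frequency at three or more times per week.
    """
    if group_col not in cohort.columns:
        raise SchemaError(f"grouping column {group_col!r} not in cohort")
    groups = [g for g in cohort[group_col].dropna().unique()]
    groups = sorted(groups, key=str)
    rows = []
    for g in groups:
        sub = cohort[cohort[group_col] == g]
        row = {"group": g, "n": len(sub)}
        for c in continuous:
            if c in sub.columns:
                vals = sub[c].astype(float)
                row[f"{c}_mean"] = float(vals.mean())
                row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        for c in categorical:
            if c in sub.columns:
                vc = sub[c].value_counts()
                for level, cnt in vc.items():
                    row[f"{c}={level}_n"] = int(cnt)
                    row[f"{c}={level}_pct"] = 100.0 * cnt / len(sub)
        rows.append(row)
    summary = pd.DataFrame(rows)

    effects = {}
    if diet_group_col is not None:
        hi = cohort[cohort[diet_group_col] == 1]["alcohol_units"]
        lo = cohort[cohort[diet_group_col] == 0]["alcohol_units"]
        effects["cohens_d_alcohol_units"] = cohens_d(hi, lo)
        freq_band = cohort["alcohol_frequency"].isin(frequency_band_levels)
        tab = np.zeros((2, 2))
        for i, dgrp in enumerate((0, 1)):
            mask = cohort[diet_group_col] == dgrp
            tab[i, 0] = int((mask & ~freq_band).sum())
            tab[i, 1] = int((mask & freq_band).sum())
        effects["phi_alcohol_frequency"] = phi_coefficient(tab)
        effects["frequency_band_table"] = tab.tolist()
    return summary, effects
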