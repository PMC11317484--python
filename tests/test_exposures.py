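"""Exposure-derivation tests: alcohol banding and metabolic thresholds at
their quoted boundaries, joint categories, exclusion filters and the
descriptive effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aldiet.errors import SchemaError
from aldiet.exposures import (
    JOINT_LABELS,
    apply_exclusions,
    categorize_alcohol,
    cohens_d,
    descriptives,
    joint_category,
    metabolic_flags,
    phi_coefficient,
)


class TestAlcoholBands:
    @pytest.mark.parametrize(
        "units,sex,expected",
        [
            (0.0, "woman", "lower"),
            (14.0, "woman", "lower"),
            (14.0, "man", "lower"),
            (14.5, "man", "increasing"),  # boundary convention: lower <= 14 < increasing
            (15.0, "woman", "increasing"),
            (34.0, "woman", "increasing"),
            (34.9, "woman", "increasing"),
            (35.0, "woman", "higher"),
            (49.0, "man", "increasing"),
            (49.9, "man", "increasing"),
            (50.0, "man", "higher"),
            (120.0, "woman", "higher"),
        ],
    )
    def test_quoted_boundaries(self, units, sex, expected):
        assert categorize_alcohol(units, sex) == expected

    def test_negative_units(self):
        with pytest.raises(ValueError):
            categorize_alcohol(-1.0, "man")

    @settings(deadline=None, max_examples=50)
    @given(sex=st.sampled_from(["woman", "man"]),
           u=st.lists(st.floats(0, 100), min_size=2, max_size=8))
    def test_step_function_monotone(self, sex, u):
        order = {"lower": 0, "increasing": 1, "higher": 2}
        u = sorted(u)
        cats = [order[categorize_alcohol(x, sex)] for x in u]
        assert cats == sorted(cats)


class TestMetabolicFlags:
    def _flags(self, **kw):
        base = dict(waist_cm=80.0, glucose_mmol_l=5.0, sbp_mmhg=120.0,
                    dbp_mmhg=80.0, tg_mmol_l=1.0, hdl_mmol_l=1.6,
                    diabetes_dx=False, htn_dx=False, sex="woman")
        base.update(kw)
        return metabolic_flags(**base).iloc[0]

    def test_central_obesity_strict_boundary(self):
        assert self._flags(waist_cm=89.0)["central_obesity"] == 1
        assert self._flags(waist_cm=88.0)["central_obesity"] == 0
        assert self._flags(waist_cm=102.0, sex="man", hdl_mmol_l=1.2)["central_obesity"] == 0
        assert self._flags(waist_cm=102.1, sex="man", hdl_mmol_l=1.2)["central_obesity"] == 1

    def test_hyperglycaemia_inclusive(self):
        assert self._flags(glucose_mmol_l=5.6)["hyperglycaemia"] == 1
        assert self._flags(glucose_mmol_l=5.59)["hyperglycaemia"] == 0
        assert self._flags(glucose_mmol_l=4.0, diabetes_dx=True)["hyperglycaemia"] == 1

    def test_hypertension_and_or(self):
        assert self._flags(sbp_mmhg=130.0)["hypertension"] == 1
        assert self._flags(sbp_mmhg=129.0, dbp_mmhg=85.0)["hypertension"] == 1
        assert self._flags(sbp_mmhg=129.0, dbp_mmhg=84.9)["hypertension"] == 0
        assert self._flags(htn_dx=True)["hypertension"] == 1

    def test_lipids_boundaries(self):
        assert self._flags(tg_mmol_l=1.7)["high_tg"] == 1
        assert self._flags(tg_mmol_l=1.69)["high_tg"] == 0
        assert self._flags(hdl_mmol_l=1.3)["low_hdl"] == 0  # strict "<"
        assert self._flags(hdl_mmol_l=1.29)["low_hdl"] == 1
        assert self._flags(hdl_mmol_l=1.0, sex="man", waist_cm=90)["low_hdl"] == 0
        assert self._flags(hdl_mmol_l=0.99, sex="man", waist_cm=90)["low_hdl"] == 1

    def test_missing_propagates_unless_diagnosed(self):
        row = self._flags(glucose_mmol_l=np.nan)
        assert np.isnan(row["hyperglycaemia"])
        row = self._flags(glucose_mmol_l=np.nan, diabetes_dx=True)
        assert row["hyperglycaemia"] == 1
        row = self._flags(sbp_mmhg=np.nan, dbp_mmhg=90.0)
        assert row["hypertension"] == 1  # one high measurement decides
        row = self._flags(sbp_mmhg=np.nan, dbp_mmhg=80.0)
        assert np.isnan(row["hypertension"])  # cannot rule out high SBP


class TestJointCategory:
    def test_reference_cell(self):
        assert joint_category(0, "lower") == "lower_diet_lower_alcohol"

    def test_top_cell(self):
        assert joint_category(1, "higher") == "higher_diet_higher_alcohol"

    def test_bijection(self):
        labels = {
            joint_category(d, a)
            for d in (0, 1)
            for a in ("lower", "increasing", "higher")
        }
        assert labels == set(JOINT_LABELS)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            joint_category(1, "extreme")


class TestExclusions:
    def _cohort(self):
        base = {
            "participant_id": range(1, 7),
            "baseline_exclusion_flag": [True, False, False, False, False, False],
            "diet_item_7": [1.0, np.nan, 1.0, 2.0, 0.0, 3.0],
            "age": [50.0] * 6,
            "sex": ["man"] * 6,
            "alcohol_units": [5.0, 5.0, np.nan, 5.0, 5.0, 5.0],
            "followup_years": [5.0, 5.0, 5.0, 1.9, 1.5, 5.0],
            "event": [0, 0, 0, 1, 0, 1],
        }
        return pd.DataFrame(base)

    def test_rules_in_order_partition(self):
        df = self._cohort()
        out, log = apply_exclusions(
            df, ["diet_item_7"], covariate_columns=["age", "sex", "alcohol_units"]
        )
        assert log.baseline_condition == 1
        assert log.missing_diet == 1
        assert log.missing_covariates == 1
        assert log.landmark_events == 1  # event at 1.9 years removed
        assert log.n_retained == 2
        # the early-censored participant (1.5y, event=0) is retained
        assert 5 in out["participant_id"].values

    def test_clean_cohort_untouched(self, small_cohort):
        out, log = apply_exclusions(small_cohort, [f"diet_item_{k}" for k in range(1, 21)])
        removed_counts = (log.baseline_condition, log.missing_diet, log.missing_covariates)
        assert removed_counts == (0, 0, 0)
        assert log.n_input - log.landmark_events == log.n_retained

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            apply_exclusions(self._cohort(), ["diet_item_99"])


class TestEffectSizes:
    def test_cohens_d_equal_means(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_phi_perfect_association(self):
        assert phi_coefficient([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_phi_hand_table(self):
        # chi2 on (30,20;20,30) is 4.0 at n=100 -> phi = 0.2
        assert phi_coefficient([[30, 20], [20, 30]]) == pytest.approx(0.2)

    def test_descriptives_bundle(self, small_cohort):
        df = small_cohort.copy()
        df["diet_high"] = (np.arange(len(df)) % 2).astype(float)
        df["grp"] = np.where(df["alcohol_units"] > 14, "ge14", "lt14")
        summary, effects = descriptives(df, "grp", diet_group_col="diet_high")
        assert set(summary["group"]) == {"ge14", "lt14"}
        assert summary["n"].sum() == len(df)
        assert "cohens_d_alcohol_units" in effects
        assert abs(effects["phi_alcohol_frequency"]) <= 1.0
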