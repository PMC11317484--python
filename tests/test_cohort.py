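"""Synthetic-cohort generator tests: determinism, survival closed forms,
baseline-rate calibration and the copula correlation bound."""

import io

import numpy as np
import pandas as pd
import pytest

from aldiet.cohort import (
    TrueEffects,
    calibrate_baseline_rate,
    default_config,
    generate_cohort,
    generate_survival,
    write_cohort_csv,
)
from aldiet.errors import CalibrationError, ConfigurationError


class TestDeterminism:
    def test_same_config_same_table(self):
        cfg = default_config(n_participants=2000, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(default_config(n_participants=2000, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_csv_byte_identical(self, tmp_path):
        cfg = default_config(n_participants=500, seed=7)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(generate_cohort(cfg), p1)
        write_cohort_csv(generate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        a = generate_cohort(default_config(n_participants=500, seed=1))
        b = generate_cohort(default_config(n_participants=500, seed=2))
        assert not a.equals(b)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        cfg = default_config(n_participants=10)
        cfg.diet_item_marginals["beef"] = (0.5, 0.5, 0.5, 0.0, 0.0)
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_nonpositive_baseline_rate(self):
        with pytest.raises(ConfigurationError):
            default_config(n_participants=10, baseline_rate=0.0)

    def test_missing_cell_loghr(self):
        with pytest.raises(ConfigurationError):
            default_config(
                n_participants=10,
                true_effects=TrueEffects(kind="joint_cells", cell_log_hrs={}),
            )

    def test_roundtrip_dict(self):
        cfg = default_config(n_participants=50, seed=3)
        clone = type(cfg).from_dict(cfg.to_dict())
        assert generate_cohort(clone).equals(generate_cohort(cfg))

    def test_roundtrip_yaml_file(self, tmp_path):
        import yaml

        cfg = default_config(n_participants=40, seed=9)
        path = tmp_path / "gen.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        clone = type(cfg).from_file(path)
        assert generate_cohort(clone).equals(generate_cohort(cfg))


class TestGenerateSurvival:
    def test_closed_form_event_rate(self):
        """With lp = 0 the event fraction is 1 - exp(-rate * censor)."""
        rng = np.random.default_rng(0)
        n = 100_000
        rate, censor = 0.05, 5.0
        _, event = generate_survival(np.zeros(n), rate, np.full(n, censor), rng)
        expected = 1 - np.exp(-rate * censor)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(event.mean() - expected) < 4 * se

    def test_offset_log2_fits_hr2(self):
        from aldiet.cox import fit_cox

        rng = np.random.default_rng(1)
        n = 40_000
        g = (np.arange(n) % 2).astype(float)
        t, d = generate_survival(np.log(2.0) * g, 0.02, np.full(n, 8.0), rng)
        fit = fit_cox(g, t, d)
        se = np.sqrt(fit.covariance[0, 0])
        assert abs(fit.coefficients[0] - np.log(2.0)) < 3 * se

    def test_rate_to_zero_limit(self):
        rng = np.random.default_rng(2)
        _, event = generate_survival(np.zeros(5000), 1e-9, np.full(5000, 10.0), rng)
        assert event.sum() == 0

    def test_weibull_shape_one_matches_exponential_distribution(self):
        rng = np.random.default_rng(3)
        t1, _ = generate_survival(np.zeros(50_000), 0.1, np.full(50_000, 50.0),
                                  np.random.default_rng(3), law="exponential")
        t2, _ = generate_survival(np.zeros(50_000), 0.1, np.full(50_000, 50.0),
                                  np.random.default_rng(3), law="weibull", shape=1.0)
        np.testing.assert_allclose(t1, t2)

    def test_invalid_censor(self):
        with pytest.raises(ConfigurationError):
            generate_survival(np.zeros(2), 0.1, np.array([1.0, 0.0]),
                              np.random.default_rng(0))


class TestCohortInvariants:
    def test_schema_and_bounds(self, small_cohort):
        t = small_cohort
        assert (t["followup_years"] > 0).all()
        assert set(t["event"].unique()) <= {0, 1}
        assert t["followup_years"].max() <= 11.4 + 1e-9
        for k in range(1, 21):
            col = t[f"diet_item_{k}"]
            assert col.min() >= 0 and col.max() <= 4
        assert set(t["sex"].unique()) <= {"woman", "man"}

    def test_diet_correlation_bounded(self):
        """Latent correlation below 0.3 keeps achieved ordinal item
        correlations within the declared 0.3 + 0.02 tolerance."""
        cfg = default_config(n_participants=20_000, seed=5, diet_correlation=0.28)
        t = generate_cohort(cfg)
        X = t[[f"diet_item_{k}" for k in range(1, 21)]].to_numpy()
        C = np.corrcoef(X.T)
        np.fill_diagonal(C, 0.0)
        assert C.max() <= 0.32

    def test_event_fraction_monotone_in_rate(self):
        fracs = []
        for rate in (1e-4, 1e-3, 1e-2):
            t = generate_cohort(default_config(n_participants=20_000, seed=9,
                                               baseline_rate=rate))
            fracs.append(t["event"].mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_null_effects_cell_hrs_near_one(self):
        """All-zero true effects: fitted pairwise joint-cell HRs ~ 1."""
        from aldiet.cox import fit_cox

        effects = TrueEffects(
            kind="joint_cells", alcohol_form="binary14",
            cell_log_hrs={"d1_a0": 0.0, "d0_a1": 0.0, "d1_a1": 0.0},
        )
        cfg = default_config(n_participants=30_000, seed=21,
                             baseline_rate=3e-3, true_effects=effects)
        t = generate_cohort(cfg)
        score = np.zeros(len(t))
        from aldiet.score import DEFAULT_LEDGER

        for name, coef in cfg.score_coefficients.items():
            score += coef * t[DEFAULT_LEDGER.column_for(name)].to_numpy()
        diet = (score >= np.median(score)).astype(float)
        alc = (t["alcohol_units"].to_numpy() > 14).astype(float)
        X = np.column_stack([diet * (1 - alc), (1 - diet) * alc, diet * alc])
        fit = fit_cox(X, t["followup_years"].to_numpy(), t["event"].to_numpy())
        ses = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(fit.coefficients) < 3.5 * ses)

    def test_missingness_injected(self):
        cfg = default_config(n_participants=5000, seed=4, missingness_prob=0.1)
        t = generate_cohort(cfg)
        frac = t["diet_item_1"].isna().mean()
        assert 0.07 < frac < 0.13
        assert t["followup_years"].notna().all()


class TestCalibration:
    def test_hits_printed_incidence(self):
        cfg = default_config(n_participants=60_000, seed=42)
        rate = calibrate_baseline_rate(cfg, 0.002)
        cfg.baseline_rate = rate
        frac = generate_cohort(cfg)["event"].mean()
        assert 0.0018 <= frac <= 0.0022

    def test_zero_target_error(self):
        with pytest.raises(CalibrationError):
            calibrate_baseline_rate(default_config(n_participants=100), 0.0)

    def test_rare_event_rate_scales_linearly(self):
        """Doubling a rare-event target roughly doubles the rate."""
        cfg = default_config(n_participants=30_000, seed=6)
        r1 = calibrate_baseline_rate(cfg, 0.002)
        r2 = calibrate_baseline_rate(cfg, 0.004)
        assert r2 / r1 == pytest.approx(2.0, rel=0.05)
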