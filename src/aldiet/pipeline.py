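"""End-to-end analysis pipeline: simulate (or load) a cohort, apply
exclusions, select score items by cross-validated LASSO, build and
dichotomise the diet score, fit the joint diet-by-alcohol Cox model,
compute additive/multiplicative interaction and attributable fractions,
and fit the penalised-spline dose-response, persisting every artifact.

All stochastic stages consume one root seed. A manifest records the
package version, seed and a hash of the resolved configuration so two
runs with the same config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GeneratorConfig, default_config, generate_cohort, write_cohort_csv
from .cox import concordance_index, fit_cox, hazard_ratios, schoenfeld_check
from .errors import SchemaError
from .exposures import (
    ALCOHOL_LEVELS,
    JOINT_LABELS,
    apply_exclusions,
    categorize_alcohol,
    descriptives,
    joint_category,
    metabolic_flags,
)
from .interaction import interaction_from_fit, paf
from .lasso import cross_validate_path
from .score import (
    DEFAULT_LEDGER,
    DietScoreModel,
    build_score,
    dichotomize_score,
    encode_items,
)
from .splines import fit_spline_cox, hr_curve, stratified_curves

__all__ = ["RunConfig", "run_pipeline", "render_tables", "build_design",
           "derive_analysis_columns"]

#: reference level per categorical covariate (first = reference)
CATEGORICAL_LEVELS = {
    "sex": ["woman", "man"],
    "ethnicity": ["white", "other"],
    "smoking": ["never", "previous", "current"],
    "physical_activity": [
        "walking",
        "other_exercise",
        "strenuous_sports",
        "light_diy",
        "heavy_diy",
        "none",
    ],
    "alcohol_frequency": [
        "never",
        "special_occasions",
        "one_to_three_monthly",
        "once_twice_week",
        "three_four_week",
        "daily",
    ],
}

DEFAULT_ADJUSTMENT = [
    "age",
    "sex",
    "deprivation",
    "ethnicity",
    "smoking",
    "physical_activity",
    "central_obesity",
    "hyperglycaemia",
    "hypertension",
    "high_tg",
    "low_hdl",
    "alcohol_frequency",
]


@dataclass
class RunConfig:
    """Pipeline settings; generator settings nest a GeneratorConfig."""

    generator: GeneratorConfig = field(default_factory=default_config)
    input_path: str = None  # CSV cohort; overrides the generator when set
    seed: int = 7
    landmark_years: float = 2.0
    covariates: list = field(default_factory=lambda: list(DEFAULT_ADJUSTMENT))
    n_lambda: int = 100
    n_folds: int = 10
    selection_rule: str = "1se"  # or "min"
    interaction_alcohol: str = "three_level"  # or "binary14" for the 2x2
    paf_method: str = "levin"
    spline_basis_size: int = 10
    spline_n_weights: int = 30
    output_dir: str = "aldiet_run"

    def to_dict(self):
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig.from_dict(gen)
        return cfg


def build_design(df: pd.DataFrame, terms, extra_levels=None):
    """Reference-coded design matrix from named columns.

    Numeric columns enter as-is; columns listed in CATEGORICAL_LEVELS (or
    ``extra_levels``) expand to dummies against their declared reference
    level. Returns ``(matrix, names)``.
    """
    levels = dict(CATEGORICAL_LEVELS)
    if extra_levels:
        levels.update(extra_levels)
    cols, names = [], []
    for term in terms:
        if term not in df.columns:
            raise SchemaError(f"column {term!r} referenced by the model is absent")
        if term in levels:
            ref, *rest = levels[term]
            observed = set(df[term].dropna().unique())
            unknown = observed - set(levels[term])
            if unknown:
                raise SchemaError(f"column {term!r} has unknown levels {sorted(unknown)}")
            for lev in rest:
                if lev in observed:
                    cols.append((df[term] == lev).astype(float).to_numpy())
                    names.append(f"{term}={lev}")
        else:
            v = pd.to_numeric(df[term], errors="raise").to_numpy(dtype=float)
            cols.append(v)
            names.append(term)
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), names


def derive_analysis_columns(df: pd.DataFrame, score_model: DietScoreModel):
    """Attach diet_score, diet_high, alcohol_cat, joint_label and the five
    metabolic flags to a filtered cohort table."""
    out = df.copy()
    design, _ = encode_items(out)
    score = build_score(design, score_model)
    out["diet_score"] = score
    ind, med = dichotomize_score(score)
    score_model.median_threshold = med
    score_model.score_mean = float(score.mean())
    score_model.score_sd = float(score.std(ddof=0))
    out["diet_high"] = ind
    out["alcohol_cat"] = categorize_alcohol(
        out["alcohol_units"].to_numpy(), out["sex"].to_numpy()
    )
    out["joint_label"] = joint_category(
        out["diet_high"].to_numpy(), out["alcohol_cat"].to_numpy()
    )
    flags = metabolic_flags(
        out["waist_cm"], out["glucose_mmol_l"], out["sbp_mmhg"], out["dbp_mmhg"],
        out["tg_mmol_l"], out["hdl_mmol_l"], out["diabetes_dx"], out["htn_dx"],
        out["sex"],
    )
    flags.index = out.index
    for c in flags.columns:
        out[c] = flags[c]
    return out


def _joint_dummies(df, alcohol_form="three_level"):
    """Joint-exposure dummy matrix with the doubly-unexposed reference."""
    if alcohol_form == "three_level":
        labels = JOINT_LABELS[1:]
        mat = np.column_stack(
            [(df["joint_label"] == lab).astype(float).to_numpy() for lab in labels]
        )
        names = [f"joint={lab}" for lab in labels]
    else:  # binary14: alcohol > 14 units/week
        a = (df["alcohol_units"].to_numpy(dtype=float) > 14.0).astype(int)
        d = df["diet_high"].to_numpy(dtype=float).astype(int)
        cells = [(1, 0), (0, 1), (1, 1)]
        mat = np.column_stack(
            [((d == dd) & (a == aa)).astype(float) for dd, aa in cells]
        )
        names = ["joint=d1_a0", "joint=d0_a1", "joint=d1_a1"]
    return mat, names


def _sha256(obj) -> str:
    if isinstance(obj, dict):
        obj = {k: v for k, v in obj.items() if k != "output_dir"}
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _dump(path: Path, obj):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_np_default))


def _np_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the report bundle as a dict
    and persists it under ``config.output_dir``.

    Stage failures raise with the stage name; artifacts written before
    the failure remain on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = {}
    stage = "configure"
    try:
        # ------------------------------------------------------ simulate
        stage = "simulate"
        if config.input_path:
            cohort = pd.read_csv(config.input_path)
            required = {"followup_years", "event", "alcohol_units", "sex"}
            missing = required - set(cohort.columns)
            if missing:
                raise SchemaError(f"input cohort lacks columns {sorted(missing)}")
        else:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort = generate_cohort(gen)

        # schema check before any model computation: every referenced
        # covariate must exist in the cohort or be derivable downstream
        derivable = {
            "central_obesity", "hyperglycaemia", "hypertension",
            "high_tg", "low_hdl", "diet_score", "diet_high",
            "alcohol_cat", "joint_label",
        }
        unknown = [
            c for c in config.covariates
            if c not in cohort.columns and c not in derivable
        ]
        if unknown:
            raise SchemaError(f"model references absent columns: {unknown}")

        # ------------------------------------------------------- derive
        stage = "derive"
        diet_cols = [f"diet_item_{k}" for k in range(1, 21)]
        filtered, exclusion_log = apply_exclusions(
            cohort, diet_cols, landmark_years=config.landmark_years
        )
        _dump(outdir / "exclusion_log.json", exclusion_log.to_dict())
        bundle["exclusion_log"] = exclusion_log.to_dict()

        # ------------------------------------------------- select-score
        stage = "select-score"
        design_items, _ = encode_items(filtered)
        X_items = design_items.to_numpy(dtype=float)
        t = filtered["followup_years"].to_numpy(dtype=float)
        d = filtered["event"].to_numpy(dtype=int)
        path = cross_validate_path(
            X_items, t, d,
            n_folds=config.n_folds, seed=config.seed, n_lambda=config.n_lambda,
        )
        active = (
            path.active_set_at_1se
            if config.selection_rule == "1se"
            else path.active_set_at_min
        )
        item_names = list(design_items.columns)
        lam_sel = path.lambda_1se if config.selection_rule == "1se" else path.lambda_min
        coefs_at_sel = path.coefficients_at(lam_sel)
        selected = [item_names[j] for j in active]
        if not selected:
            # weak-signal fallback: the four largest near-unpenalised
            # coefficients, so the score stays continuous enough for a
            # non-degenerate median split
            coefs_at_sel = path.coef_matrix[:, -1]
            top = np.argsort(-np.abs(coefs_at_sel))[:4]
            selected = [item_names[j] for j in sorted(top)]
        score_model = DietScoreModel(
            selected_items=selected,
            coefficients={item_names[j]: float(coefs_at_sel[j]) for j in range(len(item_names)) if item_names[j] in selected},
        )
        _dump(
            outdir / "lasso_path.json",
            {
                "lambda_grid": path.lambda_grid,
                "lambda_min": path.lambda_min,
                "lambda_1se": path.lambda_1se,
                "cv_error_mean": path.cv_error_mean,
                "cv_error_se": path.cv_error_se,
                "cv_cindex": path.cv_cindex,
                "selected_items": selected,
                "selection_rule": config.selection_rule,
                "warnings": path.warnings,
            },
        )
        bundle["selected_items"] = selected
        pd.DataFrame(
            path.coef_matrix, index=item_names,
            columns=[f"{lam:.6g}" for lam in path.lambda_grid],
        ).to_csv(outdir / "lasso_coefficients.tsv", sep="\t")

        # -------------------------------------------------------- score
        stage = "score"
        analysis = derive_analysis_columns(filtered, score_model)
        if analysis["diet_high"].nunique() < 2:
            # a sparse selection can make the median split degenerate
            # (e.g. one item with >50% mass at its lowest level); widen to
            # the four largest near-unpenalised coefficients
            coefs_end = path.coef_matrix[:, -1]
            top = sorted(np.argsort(-np.abs(coefs_end))[:4].tolist())
            selected = [item_names[j] for j in top]
            score_model = DietScoreModel(
                selected_items=selected,
                coefficients={item_names[j]: float(coefs_end[j]) for j in top},
            )
            bundle["selected_items"] = selected
            analysis = derive_analysis_columns(filtered, score_model)
        (outdir / "score_model.json").write_text(score_model.to_json())
        _dump(outdir / "diet_coding_ledger.json", DEFAULT_LEDGER.to_dict())
        bundle["score_model"] = json.loads(score_model.to_json())

        # ---------------------------------------------------------- fit
        stage = "fit"
        Xj, j_names = _joint_dummies(analysis, config.interaction_alcohol)
        Zc, c_names = build_design(analysis, config.covariates)
        Xfit = np.hstack([Xj, Zc])
        fit = fit_cox(Xfit, analysis["followup_years"].to_numpy(dtype=float),
                      analysis["event"].to_numpy(dtype=int),
                      names=j_names + c_names)
        summary = fit.summary()
        risk = Xfit @ fit.coefficients
        summary["concordance_index"] = concordance_index(
            risk, analysis["followup_years"].to_numpy(), analysis["event"].to_numpy()
        )
        ph = schoenfeld_check(
            fit, Xfit, analysis["followup_years"].to_numpy(),
            analysis["event"].to_numpy(),
        )
        summary["schoenfeld_p"] = dict(zip(j_names + c_names, ph["p_value"]))
        _dump(outdir / "cox_fit.json", summary)
        bundle["cox_fit"] = summary

        # ----------------------------------------------------- interact
        stage = "interact"
        if config.interaction_alcohol == "three_level":
            idx10 = j_names.index("joint=higher_diet_lower_alcohol")
            idx01 = j_names.index("joint=lower_diet_higher_alcohol")
            idx11 = j_names.index("joint=higher_diet_higher_alcohol")
            note = "2x2 from the 3-level cells: higher-alcohol band vs lower"
        else:
            idx10, idx01, idx11 = 0, 1, 2
            note = "binary diet x binary alcohol (>14 units/week)"
        inter = interaction_from_fit(fit, idx10, idx01, idx11, scale_note=note)
        _dump(outdir / "interaction.json", inter.to_dict())
        bundle["interaction"] = inter.to_dict()

        # ---------------------------------------------------------- paf
        stage = "paf"
        pafs = {}
        # mutually adjusted fit: diet binary + alcohol 3-level + covariates
        diet_dummy = analysis["diet_high"].to_numpy(dtype=float)[:, None]
        alc_dummies = np.column_stack(
            [
                (analysis["alcohol_cat"] == lev).astype(float).to_numpy()
                for lev in ALCOHOL_LEVELS[1:]
            ]
        )
        Xp = np.hstack([diet_dummy, alc_dummies, Zc])
        p_names = ["diet_high", "alcohol=increasing", "alcohol=higher"] + c_names
        fit_p = fit_cox(Xp, analysis["followup_years"].to_numpy(dtype=float),
                        analysis["event"].to_numpy(dtype=int), names=p_names)
        prev_diet = float(diet_dummy.mean())
        hr_diet = float(np.exp(fit_p.coefficients[0]))
        pafs["diet_score"] = paf(
            [1 - prev_diet, prev_diet], [1.0, hr_diet],
            method=config.paf_method, fit=fit_p, hr_indices=[0],
            seed=config.seed, exposure="diet_score>=median",
        ).to_dict()
        prev_inc = float((analysis["alcohol_cat"] == "increasing").mean())
        prev_hi = float((analysis["alcohol_cat"] == "higher").mean())
        hr_inc, hr_hi = np.exp(fit_p.coefficients[1]), np.exp(fit_p.coefficients[2])
        pafs["alcohol"] = paf(
            [1 - prev_inc - prev_hi, prev_inc, prev_hi],
            [1.0, float(hr_inc), float(hr_hi)],
            method=config.paf_method, fit=fit_p, hr_indices=[1, 2],
            seed=config.seed, exposure="alcohol risk band",
        ).to_dict()
        _dump(outdir / "paf.json", pafs)
        bundle["paf"] = pafs

        # ------------------------------------------------------- spline
        stage = "spline"
        score_vals = analysis["diet_score"].to_numpy(dtype=float)
        sp_cov = [c for c in config.covariates if c != "alcohol_frequency"]
        Zs, _ = build_design(analysis, sp_cov + ["alcohol_frequency"])
        sp_fit, sp_meta = fit_spline_cox(
            score_vals,
            analysis["followup_years"].to_numpy(dtype=float),
            analysis["event"].to_numpy(dtype=int),
            covariate_design=Zs,
            basis_size=config.spline_basis_size,
            n_weights=config.spline_n_weights,
        )
        curve = hr_curve(sp_fit, sp_meta)
        curve.to_table().to_csv(outdir / "spline_overall.tsv", sep="\t", index=False)
        strata = np.where(
            analysis["alcohol_units"].to_numpy(dtype=float) <= 14.0,
            "alcohol<=14", "alcohol>14",
        )
        try:
            sc = stratified_curves(
                score_vals, strata,
                analysis["followup_years"].to_numpy(dtype=float),
                analysis["event"].to_numpy(dtype=int),
                basis_size=config.spline_basis_size,
                n_weights=config.spline_n_weights,
            )
            for label, cu in sc.items():
                safe = label.replace("<=", "le").replace(">", "gt")
                cu.to_table().to_csv(outdir / f"spline_{safe}.tsv", sep="\t", index=False)
        except Exception as exc:  # strata can be empty in tiny runs
            bundle["spline_strata_warning"] = str(exc)
        bundle["spline_meta"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in sp_meta.items()
        }

        # ------------------------------------------------------- render
        stage = "render"
        analysis_out = analysis
        tables = render_tables(bundle, analysis_out)
        for name, tbl in tables.items():
            tbl.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _sha256(config.to_dict()),
            "stages_completed": [
                "simulate", "derive", "select-score", "score", "fit",
                "interact", "paf", "spline", "render",
            ],
        }
        _dump(outdir / "manifest.json", manifest)
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _sha256(config.to_dict()),
            "failed_stage": stage,
            "error": str(exc),
        }
        _dump(outdir / "manifest.json", manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def render_tables(bundle: dict, analysis: pd.DataFrame) -> dict:
    """Descriptive, interaction and attributable-fraction tables in the
    layouts of a cohort paper's Tables 1-3."""
    if "interaction" not in bundle or "paf" not in bundle:
        raise ValueError("bundle incomplete: run the pipeline first")
    # Table 1: descriptives by 4 joint groups (alcohol binarised at 14)
    four_group = np.where(
        analysis["diet_high"] == 1,
        np.where(analysis["alcohol_units"] > 14, "higher_diet_ge14", "higher_diet_lt14"),
        np.where(analysis["alcohol_units"] > 14, "lower_diet_ge14", "lower_diet_lt14"),
    )
    tmp = analysis.copy()
    tmp["four_group"] = four_group
    t1, effects = descriptives(tmp, "four_group", diet_group_col="diet_high")
    t1.insert(0, "table", "baseline_characteristics")
    bundle["descriptive_effect_sizes"] = {
        k: v for k, v in effects.items() if not isinstance(v, list)
    }

    inter = bundle["interaction"]
    rows = [
        {"cell": "reference", "hr": 1.0, "lower95": np.nan, "upper95": np.nan},
    ]
    for cell in ("10", "01", "11"):
        c = inter["cell_HRs"][cell]
        rows.append(
            {"cell": cell, "hr": round(c["hr"], 2),
             "lower95": round(c["lower95"], 2), "upper95": round(c["upper95"], 2)}
        )
    rows.append(
        {"cell": "RERI", "hr": round(inter["reri"], 2),
         "lower95": round(inter["reri_ci"][0], 2),
         "upper95": round(inter["reri_ci"][1], 2)}
    )
    rows.append(
        {"cell": "multiplicative", "hr": round(inter["mult_ratio"], 2),
         "lower95": round(inter["mult_ci"][0], 2),
         "upper95": round(inter["mult_ci"][1], 2)}
    )
    t2 = pd.DataFrame(rows)

    paf_rows = []
    for name, pr in bundle["paf"].items():
        for k, (pv, hr) in enumerate(zip(pr["prevalences"], pr["hazard_ratios"])):
            paf_rows.append(
                {
                    "exposure": name,
                    "category": k,
                    "prevalence_pct": round(100 * pv, 1),
                    "hr": round(hr, 2),
                    "paf_pct": round(100 * pr["paf"], 1) if k == 0 else np.nan,
                    "paf_lower95_pct": round(100 * pr["paf_ci"][0], 1) if k == 0 else np.nan,
                    "paf_upper95_pct": round(100 * pr["paf_ci"][1], 1) if k == 0 else np.nan,
                }
            )
    t3 = pd.DataFrame(paf_rows)
    return {"table1_descriptives": t1, "table2_interaction": t2, "table3_paf": t3}
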