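"""End-to-end screening pipeline.

Stages run in a fixed order: accelerometer summaries -> study exclusions ->
cut-off derivation (or loading) -> component scoring -> prevalence tables
-> latent class comparison -> correlates models. Every artifact is written
to the output directory along with a manifest (config hash, seed, package
version) so that identical configuration and seed reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelerometry import summarize_all
from .correlates import (
    backward_eliminate,
    fit_univariate,
    hosmer_lemeshow_contrasts,
    nagelkerke_r2,
    trend_test,
    build_design,
    vif,
)
from .io import read_accel, read_cohort, write_table
from .lca import compare_models, tabulate_patterns
from .phenotype import (
    COMPONENT_NAMES,
    FrailtyPhenotype,
    apply_exclusions,
    prevalence_table,
)
from .simulate import SyntheticConfig, generate_cohort

log = logging.getLogger("frailscreen")

#: Covariates entered into the correlates models. Age and K6 are continuous
#: ("per 1 unit increment"); the rest are coded flags/categories.
DEFAULT_CORRELATE_TERMS = [
    "age", "k6", "education_years", "living_alone", "employed",
    "self_health_poor", "alcohol", "smoking", "exercise", "hobby",
    "outdoor_gt_once_week", "social_activity", "lsns6_isolated",
    "mmse_impaired", "income", "housing",
]

#: Comorbidity adjustment set forced into Model 2.
COMORBIDITY_ADJUSTMENT = [
    "cm_fracture", "cm_hypertension", "cm_heart", "cm_diabetes",
    "cm_pulmonary", "cm_digestive", "cm_osteo",
]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of (cohort_path, accel_path) or synthetic must be given.
    """

    cohort_path: str | None = None
    accel_path: str | None = None
    synthetic: SyntheticConfig | None = None
    cutoff_source: str = "derive"  # "derive", "sasaguri", or a JSON path
    lca_class_range: tuple[int, ...] = (1, 2, 3)
    lca_starts: int = 20
    lca_tol: float = 1e-8
    correlates_threshold: float = 0.05
    correlates_mode: str = "multinomial"
    stratify_gender: bool = False
    seed: int = 0
    outdir: str = "frailscreen_out"

    def __post_init__(self) -> None:
        has_files = self.cohort_path is not None and self.accel_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError(
                "exactly one of (cohort_path & accel_path) or synthetic required"
            )
        if not set(self.lca_class_range) <= {1, 2, 3, 4, 5}:
            raise ValueError("lca_class_range must be within 1-5")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _manifest(config: PipelineConfig, outputs: list[str]) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }


def _derived_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Score-derived analysis flags (NaN propagates from the source score)."""
    df = df.copy()
    df["mmse_impaired"] = np.where(df["mmse"].isna(), np.nan, (df["mmse"] < 24) * 1.0)
    df["lsns6_isolated"] = np.where(df["lsns6"].isna(), np.nan, (df["lsns6"] < 12) * 1.0)
    df["k6_symptoms"] = np.where(df["k6"].isna(), np.nan, (df["k6"] > 4) * 1.0)
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the result bundle (also written to outdir)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    bundle: dict = {}

    def save(df: pd.DataFrame, name: str) -> None:
        write_table(df, out / name)
        outputs.append(name)

    stage = "input"
    try:
        if config.synthetic is not None:
            cohort, accel = generate_cohort(config.synthetic)
            save(cohort, "cohort.csv")
            save(accel, "accelerometer.csv")
        else:
            cohort = read_cohort(config.cohort_path)
            accel = read_accel(config.accel_path)

        stage = "accelerometry"
        accel_summary = summarize_all(accel)
        save(accel_summary, "accel_summary.csv")

        stage = "exclusions"
        retained, exclusion_log = apply_exclusions(cohort, accel_summary)
        save(exclusion_log, "exclusions.csv")
        log.info("retained %d of %d participants", len(retained), len(cohort))

        stage = "cutoffs"
        scorer = FrailtyPhenotype(cutoffs=config.cutoff_source).fit(retained)
        scorer.cutoffs_.to_json(out / "cutoffs.json")
        outputs.append("cutoffs.json")

        stage = "scoring"
        assessments = scorer.transform(retained)
        save(assessments, "assessments.csv")

        stage = "prevalence"
        prev = {
            "overall": prevalence_table(assessments, "overall"),
            "gender": prevalence_table(assessments, "gender"),
            "gender_age": prevalence_table(assessments, "gender_age"),
        }
        for key, tab in prev.items():
            save(tab, f"prevalence_{key}.csv")

        stage = "lca"
        patterns = tabulate_patterns(
            assessments[list(COMPONENT_NAMES)].astype(int).to_numpy()
        )
        save(patterns, "lca_patterns.csv")
        lca_table = compare_models(
            patterns,
            class_range=config.lca_class_range,
            starts=config.lca_starts,
            tol=config.lca_tol,
            seed=config.seed,
        )
        save(lca_table, "lca_comparison.csv")
        (out / "lca_comparison.json").write_text(
            lca_table.to_json(orient="records", indent=2)
        )
        outputs.append("lca_comparison.json")

        stage = "correlates"
        analysis = _derived_flags(
            retained.merge(assessments[["id", "status"]], on="id", validate="1:1")
        )
        trend_rows = []
        for term in DEFAULT_CORRELATE_TERMS:
            statistic, p = trend_test(analysis[term], analysis["status"])
            trend_rows.append({"term": term, "cmh_statistic": statistic, "p": p})
        save(pd.DataFrame(trend_rows), "correlates_trend.csv")

        uni = fit_univariate(analysis, DEFAULT_CORRELATE_TERMS,
                             mode=config.correlates_mode)
        save(uni, "correlates_univariate.csv")

        model1, trace1 = backward_eliminate(
            analysis, DEFAULT_CORRELATE_TERMS,
            threshold=config.correlates_threshold, mode=config.correlates_mode,
        )
        t1 = model1.table.copy()
        t1["model"] = "model1"
        save(t1, "correlates_model1.csv")
        save(trace1, "correlates_model1_trace.csv")

        model2, trace2 = backward_eliminate(
            analysis, DEFAULT_CORRELATE_TERMS + COMORBIDITY_ADJUSTMENT,
            threshold=config.correlates_threshold,
            forced=COMORBIDITY_ADJUSTMENT, mode=config.correlates_mode,
        )
        t2 = model2.table.copy()
        t2["model"] = "model2"
        save(t2, "correlates_model2.csv")
        save(trace2, "correlates_model2_trace.csv")

        diagnostics = {
            "n_complete_model1": model1.n,
            "n_dropped_model1": model1.n_dropped,
            "nagelkerke_r2_model1": nagelkerke_r2(
                model1.loglik, model1.loglik_null, model1.n
            ),
            "nagelkerke_r2_model2": nagelkerke_r2(
                model2.loglik, model2.loglik_null, model2.n
            ),
            "vif": vif(
                build_design(
                    analysis[DEFAULT_CORRELATE_TERMS].dropna(),
                    DEFAULT_CORRELATE_TERMS,
                )
            ).to_dict(),
        }
        if config.correlates_mode == "multinomial":
            diagnostics["hosmer_lemeshow_model1"] = {
                k: {"stat": v[0], "df": v[1], "p": v[2]}
                for k, v in hosmer_lemeshow_contrasts(model1).items()
            }
        (out / "diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2, sort_keys=True)
        )
        outputs.append("diagnostics.json")

        strata_results = {}
        if config.stratify_gender:
            for gender in ("male", "female"):
                sub = analysis[analysis["gender"] == gender]
                m, tr = backward_eliminate(
                    sub, DEFAULT_CORRELATE_TERMS,
                    threshold=config.correlates_threshold,
                    mode=config.correlates_mode,
                )
                tg = m.table.copy()
                tg["model"] = f"model1_{gender}"
                save(tg, f"correlates_model1_{gender}.csv")
                strata_results[gender] = m

        bundle = {
            "cohort": cohort,
            "accel_summary": accel_summary,
            "retained": retained,
            "exclusion_log": exclusion_log,
            "cutoffs": scorer.cutoffs_,
            "assessments": assessments,
            "prevalence": prev,
            "lca_patterns": patterns,
            "lca_comparison": lca_table,
            "trend": pd.DataFrame(trend_rows),
            "univariate": uni,
            "model1": model1,
            "model2": model2,
            "diagnostics": diagnostics,
            "strata": strata_results,
        }
    except Exception as exc:
        manifest = _manifest(config, outputs)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = _manifest(config, outputs)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
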