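"""End-to-end orchestration: score -> summarize -> features -> scans.

Stages run in a fixed order; each stage's outputs are written as TSV/JSON
under the output directory and recorded in a manifest. Missing optional
inputs (exposures, drivers, subclonality) cause the corresponding scans to
be skipped with a logged reason rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .associations import (
    ScanConfig,
    run_association_scan,
    run_interaction_test,
)
from .errors import DegenerateDataError, OxiscanError
from .features import (
    assemble_feature_table,
    compute_signature_proportions,
    summarize_driver_status,
)
from .lmm import ModelSpec, fit_lmm, simulated_residuals
from .scoring import (
    compute_hypoxia_scores,
    cross_signature_concordance,
    dichotomize_scores,
    summarize_scores,
    within_type_variance_fraction,
)
from .simulate import CohortBundle

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Pipeline settings (paths are handled by the CLI layer)."""

    seed: int = 0
    model_signature: str = "buffa"   # signature whose score feeds the models
    min_samples_per_type: int = 15
    min_mutated: int = 5
    interaction_gene: str = "PTEN"
    n_sim_diagnostics: int = 300
    scans: tuple[str, ...] = ("density", "drivers", "sbs", "id",
                              "subclonality")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _score_all_signatures(bundle: CohortBundle) -> pd.DataFrame:
    tables = [compute_hypoxia_scores(bundle.expression, sig)
              for sig in bundle.signatures.values()]
    return pd.concat(tables, ignore_index=True)


def _scan_features(merged: pd.DataFrame, bundle: CohortBundle,
                   config: RunConfig) -> dict[str, tuple[str, ...]]:
    """Feature families for each scan, from the merged table's columns."""
    families: dict[str, tuple[str, ...]] = {}
    if bundle.features is not None:
        families["density"] = tuple(
            c for c in bundle.features.columns if c != "sample")
    if bundle.driver_events is not None:
        families["drivers"] = tuple(
            c for c in merged.columns if c.startswith("driver_"))
    if bundle.exposures is not None:
        families["sbs"] = tuple(
            c for c in merged.columns if c.startswith("prop_SBS"))
        families["id"] = tuple(
            c for c in merged.columns if c.startswith("prop_ID"))
    if bundle.subclonality is not None:
        families["subclonality"] = ("n_subclones", "n_clonal", "n_subclonal")
    return families


def build_merged_table(bundle: CohortBundle, scores: pd.DataFrame,
                       config: RunConfig) -> pd.DataFrame:
    driver_status = None
    if bundle.driver_events is not None:
        genes = sorted(bundle.driver_events["gene"].unique())
        driver_status = summarize_driver_status(
            bundle.driver_events, bundle.covariates["sample"], genes)
    proportions = None
    if bundle.exposures is not None:
        proportions = compute_signature_proportions(bundle.exposures)
    merged = assemble_feature_table(
        bundle.covariates, scores,
        density=bundle.features,
        driver_status=driver_status,
        proportions=proportions,
        subclonality=bundle.subclonality,
        signature=config.model_signature)
    labels = dichotomize_scores(merged.set_index("sample")["hypoxia_score"])
    merged["hypoxia_class"] = (labels == "hypoxic").astype(int).to_numpy()
    return merged


def run_pipeline(bundle: CohortBundle, out_dir,
                 config: RunConfig | None = None) -> dict:
    """Execute the full analysis on a cohort bundle; returns the manifest."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []

    stage = "scoring"
    try:
        scores = _score_all_signatures(bundle)
        produced.append(str(io_mod.write_table(scores, out / "scores.tsv")))

        # per-type summaries + cross-signature concordance on the model sig
        model_scores = scores[scores["signature"] == config.model_signature]
        merged_cov = bundle.covariates.merge(model_scores, on="sample")
        summaries = summarize_scores(merged_cov["score"],
                                     merged_cov["cancer_type"])
        summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
        produced.append(str(io_mod.write_table(
            summary_df, out / "score_summary.tsv")))

        conc_rows = []
        for a, b in itertools.combinations(sorted(bundle.signatures), 2):
            res = cross_signature_concordance(
                scores[scores["signature"] == a],
                scores[scores["signature"] == b])
            conc_rows.append({"signature_a": a, "signature_b": b,
                              "rho": res.rho, "p": res.pvalue, "n": res.n})
        produced.append(str(io_mod.write_table(
            pd.DataFrame(conc_rows), out / "concordance.tsv")))

        overview = {
            "n_samples": int(merged_cov.shape[0]),
            "n_cancer_types": int(merged_cov["cancer_type"].nunique()),
            "within_type_variance_fraction": within_type_variance_fraction(
                merged_cov["score"], merged_cov["cancer_type"]),
        }

        stage = "features"
        merged = build_merged_table(bundle, scores, config)
        produced.append(str(io_mod.write_table(merged, out / "merged.tsv")))
        column_dict = {c: str(merged[c].dtype) for c in merged.columns}
        (out / "columns.json").write_text(
            json.dumps(column_dict, indent=1, sort_keys=True))
        produced.append(str(out / "columns.json"))

        stage = "association scans"
        families = _scan_features(merged, bundle, config)
        scan_results: dict[str, pd.DataFrame] = {}
        for scan in config.scans:
            if scan not in families or not families[scan]:
                log.info("scan %s skipped: required input table missing",
                         scan)
                continue
            scan_cfg = ScanConfig(
                features=families[scan],
                min_samples_per_type=config.min_samples_per_type,
                min_mutated=config.min_mutated)
            result = run_association_scan(merged, scan_cfg)
            scan_results[scan] = result
            produced.append(str(io_mod.write_table(
                result, out / f"scan_{scan}.tsv")))

        stage = "interaction test"
        driver_col = f"driver_{config.interaction_gene}"
        if driver_col in merged.columns and "polyclonal" in merged.columns:
            try:
                p_int, full, additive = run_interaction_test(
                    merged, "hypoxia_class", driver_col, "polyclonal",
                    ScanConfig(features=(),
                               min_samples_per_type=config.min_samples_per_type))
                interaction = {
                    "p_interaction": p_int,
                    "factor_a": "hypoxia_class", "factor_b": driver_col,
                    "response": "polyclonal", "n": full.n_obs,
                    "interaction_coef": float(
                        full.params[f"hypoxia_class:{driver_col}"]),
                }
            except DegenerateDataError as exc:
                interaction = {"skipped": str(exc)}
            (out / "interaction.json").write_text(
                json.dumps(interaction, indent=1, sort_keys=True))
            produced.append(str(out / "interaction.json"))
        else:
            log.info("interaction test skipped: %s or clonality absent",
                     driver_col)

        stage = "diagnostics"
        diag_feature = None
        if "density" in scan_results and len(scan_results["density"]):
            tested = scan_results["density"].dropna(subset=["p"])
            if len(tested):
                diag_feature = tested.iloc[0]["feature"]
        if diag_feature is not None:
            spec = ModelSpec(response="hypoxia_score",
                             terms=(diag_feature, "purity", "age", "sex"),
                             group="cancer_type")
            rows = merged.dropna(subset=list(dict.fromkeys(spec.columns)))
            fit = fit_lmm(rows, spec, method="ML")
            diag = simulated_residuals(fit, n_sim=config.n_sim_diagnostics,
                                       seed=config.seed)
            report = {
                "feature": diag_feature,
                "n_sim": diag.n_sim,
                "ks_statistic": diag.ks_statistic,
                "ks_pvalue": diag.ks_pvalue,
                "trend_rho": diag.trend_rho,
                "trend_pvalue": diag.trend_pvalue,
                "uniform_at_0.05": bool(diag.ks_pvalue > 0.05),
            }
            (out / "diagnostics.json").write_text(
                json.dumps(report, indent=1, sort_keys=True))
            produced.append(str(out / "diagnostics.json"))

        (out / "summary.json").write_text(
            json.dumps(overview, indent=1, sort_keys=True))
        produced.append(str(out / "summary.json"))
    except OxiscanError:
        partial = io_mod.write_manifest(out, produced, config.as_dict(),
                                        config.seed)
        log.error("pipeline halted at stage %r; partial manifest at %s",
                  stage, partial)
        raise

    manifest_path = io_mod.write_manifest(out, produced, config.as_dict(),
                                          config.seed)
    return json.loads(manifest_path.read_text())
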