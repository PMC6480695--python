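"""End-to-end orchestration: simulate/load -> score -> label -> evaluate ->
filter -> majority-vote search -> GLM, writing one TSV per stage.

Output artifacts (all under ``RunConfig.out_dir``):

========================  ====================================================
scores_<cohort>.tsv       continuous patient x marker scores per cohort
labels.tsv                responder / non-responder labels, with cohort
per_dataset_evaluations   ROC/Youden metrics per (marker, cohort)
marker_summaries.tsv      min / mean / max / delta AUC per marker
correlation_r.tsv, _p     Pearson matrices on the merged continuous scores
correlation_report.tsv    per-marker retained/excluded status
merged_calls.tsv          stacked dichotomous calls for the merged cohorts
combination_records.tsv   every majority-vote subset with confusion + AUC
marker_frequencies.tsv    marker containment among acceptable combinations
glm_coefficients.tsv      full-data GLM fit (term, estimate, SE, t, p)
glm_summary.tsv           repeated-holdout mean AUC / sensitivity / specificity
manifest.json             seed, versions and every decision toggle in force
========================  ====================================================

A stage failure halts the run with the stage name; files already written by
the failing stage are renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combine import frequency_report, merge_cohorts, pearson_filter, search_combinations
from .errors import PipelineError
from .glm import coefficient_table, fit_glm, repeated_holdout
from .io import RunConfig, map_response_categories, read_cohort, read_response_mapping, write_labels, write_scores
from .labels import assign_labels, label_balance
from .panel import GENE_SET_AGGREGATION, assemble_scores, builtin_panel
from .performance import count_tests, evaluate_marker, summarize_marker
from .simulate import default_config, generate_cohorts

logger = logging.getLogger("icb_bench")

__all__ = ["run_pipeline"]


def _stage(name: str, out_dir: Path, written: list[Path]):
    class _StageGuard:
        def __enter__(self):
            written.clear()
            return written

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                for path in written:
                    if path.exists():
                        path.rename(path.with_suffix(path.suffix + ".partial"))
                raise PipelineError(name, exc) from exc
            return False

    return _StageGuard()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns artifact paths and key summaries."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = builtin_panel()
    written: list[Path] = []
    artifacts: dict[str, Path] = {}

    # --- cohorts -----------------------------------------------------------
    with _stage("cohorts", out, written):
        if config.cohort_dir is not None:
            bundles = [read_cohort(config.cohort_dir, cid) for cid in config.cohort_ids]
        else:
            bundles = generate_cohorts(default_config(seed=config.seed))
        logger.info("cohorts: %d (%s)", len(bundles), ", ".join(b.cohort_id for b in bundles))

    # --- scoring -----------------------------------------------------------
    score_tables = {}
    with _stage("score", out, written):
        for bundle in bundles:
            table = assemble_scores(bundle, panel, dedup_mutations=config.dedup_mutations)
            score_tables[bundle.cohort_id] = table
            path = out / f"scores_{bundle.cohort_id}.tsv"
            write_scores(table.scores, path)
            written.append(path)
            artifacts[f"scores_{bundle.cohort_id}"] = path

    # --- labels ------------------------------------------------------------
    labels_by_cohort = {}
    with _stage("label", out, written):
        mapping = (
            read_response_mapping(config.response_mapping)
            if config.response_mapping is not None
            else None
        )
        rows = []
        for bundle in bundles:
            clinical = bundle.clinical
            if mapping:
                clinical = map_response_categories(clinical, mapping)
            lab = assign_labels(clinical, os_cutoff_years=config.os_cutoff_years)
            lab["cohort"] = bundle.cohort_id
            labels_by_cohort[bundle.cohort_id] = lab.set_index("patient_id")["label"]
            rows.append(lab)
            logger.info(
                "labels %s: %d patients, responder fraction %.3f",
                bundle.cohort_id, len(lab), label_balance(lab),
            )
        all_labels = pd.concat(rows, ignore_index=True)
        path = out / "labels.tsv"
        write_labels(all_labels, path)
        written.append(path)
        artifacts["labels"] = path

    # --- per-dataset evaluation -------------------------------------------
    evaluations = []
    with _stage("evaluate", out, written):
        for bundle in bundles:
            table = score_tables[bundle.cohort_id].scores
            lab = labels_by_cohort[bundle.cohort_id]
            for marker in table.columns:
                if table[marker].isna().all():
                    continue
                evaluations.append(
                    evaluate_marker(table[marker], lab, marker, bundle.cohort_id)
                )
        n_expected = count_tests(
            [b.rna_available for b in bundles], [b.dna_available for b in bundles], panel
        )
        logger.info("evaluations: %d run (%d allowed by availability)", len(evaluations), n_expected)
        frame = pd.DataFrame(
            {
                "marker": [e.marker for e in evaluations],
                "cohort": [e.cohort for e in evaluations],
                "n_patients": [e.n_patients for e in evaluations],
                "auc": [e.auc for e in evaluations],
                "orientation": [e.orientation for e in evaluations],
                "threshold": [e.threshold for e in evaluations],
                "sensitivity": [e.sensitivity for e in evaluations],
                "specificity": [e.specificity for e in evaluations],
                "youden_j": [e.youden_j for e in evaluations],
            }
        )
        path = out / "per_dataset_evaluations.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
        artifacts["per_dataset_evaluations"] = path

    # --- cross-cohort summaries -------------------------------------------
    with _stage("summarize", out, written):
        summaries = []
        for marker in dict.fromkeys(e.marker for e in evaluations):
            summaries.append(summarize_marker([e for e in evaluations if e.marker == marker]))
        summary_frame = pd.DataFrame(
            {
                "marker": [s.marker for s in summaries],
                "n_datasets": [s.n_datasets for s in summaries],
                "auc_min": [s.auc_min for s in summaries],
                "auc_mean": [s.auc_mean for s in summaries],
                "auc_max": [s.auc_max for s in summaries],
                "auc_delta": [s.auc_delta for s in summaries],
            }
        )
        path = out / "marker_summaries.tsv"
        summary_frame.to_csv(path, sep="\t", index=False)
        written.append(path)
        artifacts["marker_summaries"] = path

    # --- merge + correlation filter ---------------------------------------
    rna_cohorts = [b.cohort_id for b in bundles if b.rna_available]
    with _stage("correlation_filter", out, written):
        merged_scores_tables = {}
        for cid in rna_cohorts:
            table = score_tables[cid].scores
            keep = [c for c in table.columns if not table[c].isna().any()]
            merged_scores_tables[cid] = table[keep]
        merged_scores = merge_cohorts(
            merged_scores_tables, labels_by_cohort, rna_cohorts, restrict_to_shared=True
        )
        marker_cols = [c for c in merged_scores.columns if c not in ("label", "cohort")]
        if not config.include_mutational_load:
            marker_cols = [c for c in marker_cols if c != "Mutational load"]
        priority = summary_frame.set_index("marker")["auc_mean"].to_dict()
        report = pearson_filter(
            merged_scores[marker_cols], r_cut=config.r_cut, alpha=config.alpha, priority=priority
        )
        logger.info(
            "correlation filter: %d edges, excluded %s", len(report.edges), report.excluded
        )
        r_path, p_path = out / "correlation_r.tsv", out / "correlation_p.tsv"
        report.r.to_csv(r_path, sep="\t", index_label="marker")
        report.p.to_csv(p_path, sep="\t", index_label="marker")
        status = pd.DataFrame(
            {
                "marker": report.markers,
                "status": ["excluded" if m in report.excluded else "retained" for m in report.markers],
            }
        )
        status_path = out / "correlation_report.tsv"
        status.to_csv(status_path, sep="\t", index=False)
        written.extend([r_path, p_path, status_path])
        artifacts.update(
            correlation_r=r_path, correlation_p=p_path, correlation_report=status_path
        )

    # --- merged dichotomous calls -----------------------------------------
    with _stage("merge_calls", out, written):
        calls_tables = {}
        for cid in rna_cohorts:
            calls = pd.DataFrame(
                {e.marker: e.calls for e in evaluations if e.cohort == cid and e.marker in report.retained}
            )
            calls_tables[cid] = calls
        merged_calls = merge_cohorts(calls_tables, labels_by_cohort, rna_cohorts)
        path = out / "merged_calls.tsv"
        write_scores(merged_calls, path)
        written.append(path)
        artifacts["merged_calls"] = path
        logger.info(
            "merged calls: %d patients x %d retained markers",
            len(merged_calls), len(report.retained),
        )

    # --- exhaustive majority-vote search ----------------------------------
    with _stage("combinations", out, written):
        call_matrix = merged_calls[report.retained].astype(int)
        merged_labels = merged_calls["label"]
        records = search_combinations(
            call_matrix, merged_labels, tie_to_responder=config.tie_to_responder
        )
        freq = frequency_report(records, auc_floor=config.auc_floor)
        rec_out = records.copy()
        rec_out["combination"] = rec_out.pop("subset").map(" + ".join)
        rec_path = out / "combination_records.tsv"
        rec_out[
            ["combination", "size", "tp", "fp", "tn", "fn", "sensitivity", "specificity", "auc"]
        ].to_csv(rec_path, sep="\t", index=False)
        freq_frame = pd.DataFrame(
            {"marker": list(freq.frequency), "frequency": list(freq.frequency.values())}
        )
        freq_path = out / "marker_frequencies.tsv"
        freq_frame.to_csv(freq_path, sep="\t", index=False)
        written.extend([rec_path, freq_path])
        artifacts.update(combination_records=rec_path, marker_frequencies=freq_path)
        logger.info(
            "combinations: %d scored, %.2f%% acceptable at AUC >= %.2f",
            freq.n_records, 100 * freq.acceptable_fraction, config.auc_floor,
        )

    # --- GLM ---------------------------------------------------------------
    with _stage("glm", out, written):
        fit = fit_glm(call_matrix, merged_labels)
        coef = coefficient_table(fit)
        coef_path = out / "glm_coefficients.tsv"
        coef.to_csv(coef_path, sep="\t", index=False)
        cv = repeated_holdout(
            call_matrix,
            merged_labels,
            test_fraction=config.test_fraction,
            iterations=config.iterations,
            seed=config.seed,
        )
        cv_frame = pd.DataFrame(
            [
                {
                    "iterations": cv.iterations,
                    "valid_iterations": cv.valid_iterations,
                    "skipped_iterations": cv.skipped_iterations,
                    "mean_auc": cv.mean_auc,
                    "mean_best_sensitivity": cv.mean_best_sensitivity,
                    "mean_best_specificity": cv.mean_best_specificity,
                    "test_fraction": cv.test_fraction,
                    "seed": cv.seed,
                }
            ]
        )
        cv_path = out / "glm_summary.tsv"
        cv_frame.to_csv(cv_path, sep="\t", index=False)
        written.extend([coef_path, cv_path])
        artifacts.update(glm_coefficients=coef_path, glm_summary=cv_path)
        logger.info(
            "glm holdout: mean AUC %.3f over %d valid iterations", cv.mean_auc, cv.valid_iterations
        )

    # --- manifest ----------------------------------------------------------
    with _stage("manifest", out, written):
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "simulated": config.cohort_dir is None,
            "cohorts": [b.cohort_id for b in bundles],
            "expression_unit": config.expression_unit,
            "gene_set_aggregation": GENE_SET_AGGREGATION,
            "os_cutoff_years": config.os_cutoff_years,
            "r_cut": config.r_cut,
            "alpha": config.alpha,
            "auc_floor": config.auc_floor,
            "test_fraction": config.test_fraction,
            "iterations": config.iterations,
            "include_mutational_load": config.include_mutational_load,
            "tie_to_responder": config.tie_to_responder,
            "dedup_mutations": config.dedup_mutations,
            "orientation": "automatic (reported AUC >= 0.5, direction recorded)",
            "wald_reference": "normal approximation ('t_value' column holds the Wald z)",
            "excluded_markers": report.excluded,
            "retained_markers": report.retained,
            "n_combinations": int(len(records)),
            "acceptable_fraction": freq.acceptable_fraction,
            "glm_mean_auc": cv.mean_auc,
        }
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2) + "\n")
        written.append(man_path)
        artifacts["manifest"] = man_path

    return {
        "artifacts": artifacts,
        "bundles": bundles,
        "evaluations": evaluations,
        "summaries": summary_frame,
        "correlation": report,
        "records": records,
        "frequencies": freq,
        "glm_fit": fit,
        "glm_cv": cv,
    }
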