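#!/usr/bin/env python
"""Evaluate every marker on every cohort by ROC with Youden dichotomization.

Produces the per-dataset evaluation table (one row per marker x cohort with
AUC, orientation, cutpoint, sensitivity, specificity) and the cross-cohort
summary (min/mean/max AUC and their spread per marker), plus the per-cohort
binary calls consumed by the combination analyses.
"""

import argparse
from pathlib import Path

import pandas as pd

from icb_bench import io as iomod
from icb_bench.performance import evaluate_marker, summarize_marker

COHORTS = ["study1", "study2", "study3", "study4", "study5"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--tables", type=Path, default=Path("results/tables"))
    args = parser.parse_args()

    labels = iomod.read_labels(args.tables / "labels.tsv")
    evaluations = []
    for cid in COHORTS:
        scores = iomod.read_scores(args.tables / f"scores_{cid}.tsv")
        lab = labels.query("cohort == @cid").set_index("patient_id")["label"]
        calls = {}
        for marker in scores.columns:
            if scores[marker].isna().all():
                continue
            ev = evaluate_marker(scores[marker], lab, marker, cid)
            evaluations.append(ev)
            calls[marker] = ev.calls
        iomod.write_scores(pd.DataFrame(calls), args.tables / f"calls_{cid}.tsv")

    per = pd.DataFrame(
        {
            "marker": [e.marker for e in evaluations],
            "cohort": [e.cohort for e in evaluations],
            "n_patients": [e.n_patients for e in evaluations],
            "auc": [e.auc for e in evaluations],
            "orientation": [e.orientation for e in evaluations],
            "threshold": [e.threshold for e in evaluations],
            "sensitivity": [e.sensitivity for e in evaluations],
            "specificity": [e.specificity for e in evaluations],
        }
    )
    per.to_csv(args.tables / "per_dataset_evaluations.tsv", sep="\t", index=False)

    summaries = [
        summarize_marker([e for e in evaluations if e.marker == m])
        for m in dict.fromkeys(e.marker for e in evaluations)
    ]
    summary = pd.DataFrame(
        {
            "marker": [s.marker for s in summaries],
            "n_datasets": [s.n_datasets for s in summaries],
            "auc_min": [s.auc_min for s in summaries],
            "auc_mean": [s.auc_mean for s in summaries],
            "auc_max": [s.auc_max for s in summaries],
            "auc_delta": [s.auc_delta for s in summaries],
        }
    ).sort_values("auc_mean", ascending=False)
    summary.to_csv(args.tables / "marker_summaries.tsv", sep="\t", index=False)

    print(f"{len(per)} marker x cohort evaluations (AUC {per['auc'].min():.2f}-{per['auc'].max():.2f})")
    print("best mean AUCs across cohorts:")
    for _, row in summary.head(3).iterrows():
        print(f"  {row['marker']}: {row['auc_mean']:.2f} (delta {row['auc_delta']:.2f})")


if __name__ == "__main__":
    main()
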