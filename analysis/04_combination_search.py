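#!/usr/bin/env python
"""Merge the RNA cohorts, prune correlated markers, and exhaustively score
every majority-voting marker combination.

Pairs with |Pearson r| > 0.5 at p < 0.01 (on the merged continuous scores)
are broken by removing a minimum number of markers; every subset of >= 2
retained markers is then scored by majority vote on the merged dichotomous
calls, and marker frequencies are tallied among the combinations reaching
AUC >= 0.65.
"""

import argparse
from pathlib import Path

import pandas as pd

from icb_bench import io as iomod
from icb_bench.combine import frequency_report, merge_cohorts, pearson_filter, search_combinations

RNA_COHORTS = ["study1", "study2", "study5"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--tables", type=Path, default=Path("results/tables"))
    parser.add_argument("--auc-floor", type=float, default=0.65)
    args = parser.parse_args()

    labels_frame = iomod.read_labels(args.tables / "labels.tsv")
    labels, scores, calls = {}, {}, {}
    for cid in RNA_COHORTS:
        labels[cid] = labels_frame.query("cohort == @cid").set_index("patient_id")["label"]
        table = iomod.read_scores(args.tables / f"scores_{cid}.tsv")
        scores[cid] = table[[c for c in table.columns if not table[c].isna().any()]]
        calls[cid] = iomod.read_scores(args.tables / f"calls_{cid}.tsv")

    merged_scores = merge_cohorts(scores, labels, RNA_COHORTS, restrict_to_shared=True)
    markers = [c for c in merged_scores.columns if c not in ("label", "cohort")]
    priority = (
        pd.read_csv(args.tables / "marker_summaries.tsv", sep="\t")
        .set_index("marker")["auc_mean"]
        .to_dict()
    )
    report = pearson_filter(merged_scores[markers], priority=priority)
    print(f"correlated pairs: {report.edges}; excluded: {report.excluded or 'none'}")

    merged_calls = merge_cohorts(
        {cid: calls[cid][report.retained] for cid in RNA_COHORTS}, labels, RNA_COHORTS
    )
    records = search_combinations(merged_calls[report.retained].astype(int), merged_calls["label"])
    freq = frequency_report(records, auc_floor=args.auc_floor)

    out = records.copy()
    out["combination"] = out.pop("subset").map(" + ".join)
    out[["combination", "size", "tp", "fp", "tn", "fn", "sensitivity", "specificity", "auc"]].to_csv(
        args.tables / "combination_records.tsv", sep="\t", index=False
    )
    iomod.write_scores(merged_calls, args.tables / "merged_calls.tsv")
    pd.DataFrame(
        {"marker": list(freq.frequency), "frequency": list(freq.frequency.values())}
    ).to_csv(args.tables / "marker_frequencies.tsv", sep="\t", index=False)

    print(
        f"{freq.n_records} combinations of {len(report.retained)} retained markers scored; "
        f"{100 * freq.acceptable_fraction:.1f}% reach AUC >= {args.auc_floor}"
    )
    for marker, value in list(freq.frequency.items())[:3]:
        print(f"  most present in acceptable combinations: {marker} ({value:.2f})")


if __name__ == "__main__":
    main()
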