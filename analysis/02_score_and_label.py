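#!/usr/bin/env python
"""Score the 18-marker panel on every cohort and assign response labels.

Reads the TSVs written by 01_simulate_cohorts.py, computes continuous
per-patient marker scores (log2(TPM+1) for genes, mean thereof for
signatures, raw variant counts for mutational load, plug-in columns for
TIDE/IPS) and the dichotomous responder labels (CR/PR/SD/LB, or PD
surviving beyond 2 years).
"""

import argparse
from pathlib import Path

import pandas as pd

from icb_bench import io as iomod
from icb_bench.labels import assign_labels
from icb_bench.panel import assemble_scores

COHORTS = ["study1", "study2", "study3", "study4", "study5"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    all_labels = []
    for cid in COHORTS:
        bundle = iomod.read_cohort(args.cohorts, cid)
        table = assemble_scores(bundle)
        iomod.write_scores(table.scores, args.out / f"scores_{cid}.tsv")
        labels = assign_labels(bundle.clinical)
        labels["cohort"] = cid
        all_labels.append(labels)
        scored = int(table.scores.notna().any().sum())
        print(f"{cid}: {scored} markers scored for {len(table.scores)} patients")
    labels = pd.concat(all_labels, ignore_index=True)
    iomod.write_labels(labels, args.out / "labels.tsv")
    frac = (labels["label"] == "responder").mean()
    print(f"overall responder fraction: {frac:.2f}; tables in {args.out}")


if __name__ == "__main__":
    main()
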