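#!/usr/bin/env python
"""Entropy-window background thresholds and binary activity calls.

Computes each gene's cutoff over the healthy reference samples, binarizes
per-tissue medians, and reports recovery of the planted activity plus the
per-sample background false-activation rate of the cutoff procedure.
"""
import sys
from pathlib import Path

import pandas as pd

from kinact import call_activity, compute_thresholds
from kinact import io as kio
from kinact.studies import activity_recovery, background_false_activation

DATA = Path("results/data/activity")
OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = kio.read_expression(DATA / "expression.tsv")
    annotation = kio.read_annotation(DATA / "annotation.tsv")
    truth = kio.read_activity(DATA / "truth_activity.tsv")

    thresholds = compute_thresholds(matrix, annotation)
    activity = call_activity(matrix, annotation, thresholds)
    kio.write_thresholds(OUT / "thresholds.tsv", thresholds)
    kio.write_activity(OUT / "activity.tsv", activity)

    agree = (activity[truth.columns].to_numpy() == truth.to_numpy()).mean()
    print(f"thresholds for {len(thresholds)} genes "
          f"({(thresholds['degenerate'] != '').sum()} flagged degenerate)")
    print(f"activity calls agree with planted truth on {agree:.1%} of cells")

    recovery = activity_recovery(range(20))
    recovery.to_csv(OUT / "activity_recovery.tsv", sep="\t", index=False)
    print(
        f"recovery over 20 seeds: sensitivity {recovery['sensitivity'].mean():.3f}, "
        f"specificity {recovery['specificity'].mean():.3f}"
    )

    fa = background_false_activation(seed=0)
    pd.DataFrame([fa]).to_csv(OUT / "background_false_activation.tsv", sep="\t",
                              index=False)
    print(
        f"per-sample background exceedance of the cutoff: {fa['mean_exceedance']:.3f} "
        f"(n={fa['n_genes']} genes) — the cutoff controls the tissue-MEDIAN "
        "statistic, not individual samples"
    )


if __name__ == "__main__":
    sys.exit(main())
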