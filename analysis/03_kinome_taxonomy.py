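#!/usr/bin/env python
"""Tissue/gene taxonomy of the binary activity matrix and gain/loss calls.

Clusters both axes with the asymmetric-binary distance (complete linkage),
summarizes tissue-group composition as majority-state purity, tabulates
gene-group by tissue-group activity shares, and calls gains/losses of
activity between every paired healthy/malignant tissue.
"""
import sys
from pathlib import Path

import pandas as pd

from kinact import io as kio
from kinact.pipeline import _paired_tissues
from kinact.studies import gain_loss_mismatches
from kinact.taxonomy import (
    changed_fraction,
    cluster_binary,
    cut_groups,
    gain_loss,
    group_activity_share,
    group_purity,
)

DATA = Path("results/data/activity")
OUT = Path("results/analysis")


def main():
    activity = kio.read_activity(OUT / "activity.tsv")
    annotation = kio.read_annotation(DATA / "annotation.tsv")

    tissue_tree = cluster_binary(activity, "tissues", "complete")
    gene_tree = cluster_binary(activity, "genes", "complete")
    kio.write_newick(OUT / "tissue_tree.nwk", tissue_tree.linkage, tissue_tree.items)
    kio.write_newick(OUT / "gene_tree.nwk", gene_tree.linkage, gene_tree.items)

    tissue_groups = cut_groups(tissue_tree, 4)
    gene_groups = cut_groups(gene_tree, 6)
    state_of = dict(
        annotation.drop_duplicates("tissue_type")[["tissue_type", "state"]].values
    )
    purity = group_purity(tissue_groups, state_of)
    purity.to_csv(OUT / "tissue_group_purity.tsv", sep="\t")
    print("tissue-group purity (majority state):")
    print(purity.to_string())

    shares = []
    for gg in sorted(set(gene_groups.values())):
        genes = [g for g, c in gene_groups.items() if c == gg]
        for tg in sorted(set(tissue_groups.values())):
            tissues = [t for t, c in tissue_groups.items() if c == tg]
            shares.append({
                "gene_group": gg, "tissue_group": tg,
                "activity_share_pct": round(
                    group_activity_share(activity, genes, tissues), 1
                ),
            })
    shares = pd.DataFrame(shares)
    shares.to_csv(OUT / "group_activity_share.tsv", sep="\t", index=False)

    rows = []
    for ref, cmp_ in _paired_tissues(activity.columns):
        report = gain_loss(activity, ref, cmp_)
        rows.append({
            "reference": ref, "comparison": cmp_,
            "n_gained": len(report.gained), "n_lost": len(report.lost),
            "changed_pct": changed_fraction(report),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "gainloss_summary.tsv", sep="\t", index=False)
    print("\ngain/loss per paired tissue:")
    print(summary.to_string(index=False))

    mism = gain_loss_mismatches(seed=0)
    print(
        f"\ngenes whose called gain/loss status deviates from planted truth: "
        f"{mism['mismatched_genes'] or 'none'}"
    )


if __name__ == "__main__":
    sys.exit(main())
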