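#!/usr/bin/env python
"""Generate the two synthetic study corpora with planted truth.

Corpus A (activity study): 40 genes x 30 tissues x 20 samples, 8-SD active
shift, 5% missing — used for threshold calling, taxonomy and gain/loss.
Corpus B (co-expression study): 1500 genes x 99 tissues x 6 samples with
five 20-gene modules under a strong shared factor — used for the
correlation-graph walks and enrichment.
"""
import dataclasses
import sys
from pathlib import Path

import pandas as pd

from kinact import io as kio
from kinact import simulate_expression, simulate_ontology
from kinact.studies import COEXPRESSION_CONFIG, RECOVERY_CONFIG

OUT = Path("results/data")


def write_corpus(name, config):
    outdir = OUT / name
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, annotation, truth = simulate_expression(config)
    ontology = simulate_ontology(config)
    kio.write_expression(outdir / "expression.tsv", matrix)
    kio.write_annotation(outdir / "annotation.tsv", annotation)
    kio.write_obo(outdir / "ontology.obo", ontology)
    kio.write_gmt(
        outdir / "annotations.gmt",
        {t: ontology.genes(t) for t in ontology.terms if ontology.genes(t)},
        descriptions=ontology.names,
    )
    kio.write_activity(outdir / "truth_activity.tsv", truth.true_activity)
    pd.Series(truth.module_membership, name="module").rename_axis("gene").to_csv(
        outdir / "truth_modules.tsv", sep="\t"
    )
    pd.Series(truth.marker_genes, name="marker").rename_axis("module").to_csv(
        outdir / "truth_markers.tsv", sep="\t"
    )
    print(
        f"{name}: {matrix.shape[0]} genes x {matrix.shape[1]} samples, "
        f"{truth.true_activity.to_numpy().sum()} planted active gene-tissue pairs"
    )


def main():
    write_corpus("activity", dataclasses.replace(RECOVERY_CONFIG, seed=0))
    write_corpus("coexpression", dataclasses.replace(COEXPRESSION_CONFIG, seed=3))


if __name__ == "__main__":
    sys.exit(main())
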