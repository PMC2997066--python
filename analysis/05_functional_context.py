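#!/usr/bin/env python
"""Functional-context associations: enrichment, term matrix and ordering.

Tests every module gene's walk neighborhood for term over-representation
(hypergeometric, p < 0.01, no correction), assembles the binary seed x term
association matrix, filters terms shared by >= 15 seed genes, and orders
the retained terms by Lin similarity under Ward linkage.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from kinact import enrich_set, filter_terms, kinase_term_matrix, semantic_ordering
from kinact import io as kio

DATA = Path("results/data/coexpression")
OUT = Path("results/analysis")


def main():
    matrix = kio.read_expression(DATA / "expression.tsv")
    modules = pd.read_csv(DATA / "truth_modules.tsv", sep="\t", index_col=0)["module"]
    ontology = kio.ontology_from_obo(
        DATA / "ontology.obo", DATA / "annotations.gmt", universe=list(matrix.index)
    )
    hoods = pd.read_csv(OUT / "neighborhoods.tsv", sep="\t")

    tables = {}
    for gene in sorted(modules.index):
        genes = hoods.loc[hoods["seed"] == gene, "gene"]
        tables[gene] = enrich_set(genes, ontology, alpha=0.01)
    combined = pd.concat(
        [t.assign(seed=s) for s, t in tables.items() if len(t)], ignore_index=True
    )
    combined.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    term_matrix = kinase_term_matrix(tables)
    term_matrix.to_csv(OUT / "seed_term_matrix.tsv", sep="\t")
    filtered = filter_terms(term_matrix, min_seeds=15)
    filtered.to_csv(OUT / "seed_term_matrix_filtered.tsv", sep="\t")
    print(f"{int(term_matrix.to_numpy().sum())} accepted seed-term associations; "
          f"{filtered.shape[1]} terms shared by >= 15 seed genes")

    # does each module gene associate with its own module's designated term?
    own_term = {g: f"T{modules[g] + 1:03d}" for g in modules.index}
    hit = [
        bool(term_matrix.loc[g, own_term[g]]) if own_term[g] in term_matrix.columns
        else False
        for g in modules.index
    ]
    print(f"fraction of module genes associated with their own module's term: "
          f"{np.mean(hit):.2f}")

    if filtered.shape[1] >= 2:
        ordering = semantic_ordering(list(filtered.columns), ontology)
        kio.write_newick(OUT / "term_ordering.nwk", ordering.linkage,
                         ordering.ordered_terms)
        (OUT / "term_order.txt").write_text("\n".join(ordering.ordered_terms) + "\n")
        print("semantic term ordering:", " ".join(ordering.ordered_terms))


if __name__ == "__main__":
    sys.exit(main())
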