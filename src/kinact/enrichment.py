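"""Over-representation tests, seed-by-term associations and Lin ordering.

Neighborhood gene sets are tested per ontology term with the one-sided
hypergeometric tail; enrichments with p < 0.01 are accepted (no
multiple-testing correction by default, an optional Benjamini-Hochberg
switch is provided).  Accepted terms across seed genes form a binary
seed x term matrix, filtered to terms shared by at least ``min_seeds``
seeds.  Term ordering for presentation uses Lin semantic similarity
(information content from the ontology's own annotation frequencies) under
Ward linkage.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import false_discovery_control, hypergeom

from .ontology import Ontology

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentTable",
    "TermOrdering",
    "hypergeometric_tail",
    "enrich_set",
    "kinase_term_matrix",
    "filter_terms",
    "information_content",
    "lin_similarity",
    "semantic_ordering",
]

ENRICHMENT_COLUMNS = [
    "term",
    "overlap",
    "set_size",
    "term_size",
    "universe_size",
    "p_value",
    "accepted",
]

#: Per-seed enrichment results; one row per term with non-zero overlap.
EnrichmentTable = pd.DataFrame


@dataclass
class TermOrdering:
    """Terms ordered by the leaves of a Ward tree over 1 - Lin similarity."""

    ordered_terms: List[str]
    similarity: pd.DataFrame
    linkage: np.ndarray


def hypergeometric_tail(overlap: int, set_size: int, term_size: int, universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, term_size, set_size)."""
    if not (0 <= overlap <= min(set_size, term_size) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, set={set_size}, "
            f"term={term_size}, universe={universe}"
        )
    if max(set_size, term_size) > universe:
        raise ValueError("set and term sizes cannot exceed the universe")
    p = float(hypergeom.sf(overlap - 1, universe, term_size, set_size))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def enrich_set(
    genes: Iterable[str],
    ontology: Ontology,
    alpha: float = 0.01,
    universe: Optional[Iterable[str]] = None,
    bh_correction: bool = False,
) -> EnrichmentTable:
    """Hypergeometric over-representation of every ontology term in a gene set.

    ``universe`` defaults to the ontology's own gene universe; genes outside
    it are logged and dropped.  One row per term with non-zero overlap;
    ``accepted`` is ``p < alpha`` (on BH-adjusted p-values if requested).
    """
    uni = frozenset(universe) if universe is not None else ontology.universe
    gene_set = set(genes)
    outside = gene_set - uni
    if outside:
        log.warning(
            "%d genes outside the universe dropped, e.g. %s",
            len(outside),
            sorted(outside)[:3],
        )
        gene_set &= uni
    if not gene_set:
        log.warning("empty neighborhood; empty enrichment table")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    N, n = len(uni), len(gene_set)
    rows = []
    for term in sorted(ontology.terms):
        term_genes = ontology.genes(term) & uni
        k = len(term_genes & gene_set)
        if k == 0:
            continue
        K = len(term_genes)
        rows.append((term, k, n, K, N, hypergeometric_tail(k, n, K, N)))
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if table.empty:
        table["accepted"] = pd.Series(dtype=bool)
        return table
    pvals = table["p_value"].to_numpy()
    if bh_correction:
        pvals = false_discovery_control(pvals)
        table["p_adjusted"] = pvals
    table["accepted"] = pvals < alpha
    return table.sort_values(["p_value", "term"], ignore_index=True)


def kinase_term_matrix(tables: Mapping[str, EnrichmentTable]) -> pd.DataFrame:
    """Binary seed x term matrix of accepted enrichments."""
    all_terms = sorted(
        {t for table in tables.values() if len(table) for t in table["term"]}
    )
    out = pd.DataFrame(0, index=list(tables), columns=all_terms, dtype=np.int8)
    for seed, table in tables.items():
        if len(table) == 0:
            continue
        accepted = table.loc[table["accepted"], "term"]
        out.loc[seed, list(accepted)] = 1
    out.index.name = "seed"
    out.columns.name = "term"
    return out


def filter_terms(matrix: pd.DataFrame, min_seeds: int = 15) -> pd.DataFrame:
    """Keep terms accepted for at least ``min_seeds`` seed genes."""
    return matrix.loc[:, matrix.sum(axis=0) >= min_seeds]


def information_content(term: str, ontology: Ontology) -> float:
    """IC(t) = -ln(|genes(t)| / |genes(root)|); 0 for the root."""
    n_term = len(ontology.genes(term))
    n_root = len(ontology.genes(ontology.root))
    if n_term == 0 or n_root == 0:
        raise ValueError(f"term {term!r} annotates no genes; IC undefined")
    return -math.log(n_term / n_root)


def lin_similarity(t1: str, t2: str, ontology: Ontology) -> float:
    """Lin similarity 2*IC(MICA) / (IC(t1) + IC(t2)) in [0, 1].

    The MICA is the common ancestor with maximal IC (ties broken towards
    the smallest term id).  sim(t, t) = 1; terms whose only common ancestor
    is the root have similarity 0.
    """
    if t1 == t2:
        return 1.0
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    if not common:
        raise ValueError(f"{t1!r} and {t2!r} share no ancestor (not a rooted DAG?)")
    ic = {t: information_content(t, ontology) for t in common}
    mica = min(common, key=lambda t: (-ic[t], t))
    denom = information_content(t1, ontology) + information_content(t2, ontology)
    if denom == 0:
        return 0.0
    return min(max(2.0 * ic[mica] / denom, 0.0), 1.0)


def semantic_ordering(
    terms: Sequence[str], ontology: Ontology, method: str = "ward"
) -> TermOrdering:
    """Order terms by the leaf sequence of a Ward tree on 1 - Lin similarity."""
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("need at least 2 terms to order")
    sim = pd.DataFrame(1.0, index=terms, columns=terms)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            s = lin_similarity(t1, t2, ontology)
            sim.loc[t1, t2] = s
            sim.loc[t2, t1] = s
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = [terms[i] for i in hierarchy.leaves_list(Z)]
    return TermOrdering(order, sim, Z)
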