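"""Hypergeometric enrichment, term matrices and Lin semantic ordering."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from kinact import (
    Ontology,
    enrich_set,
    filter_terms,
    hypergeometric_tail,
    information_content,
    kinase_term_matrix,
    lin_similarity,
    semantic_ordering,
)

from oracles import hypergeom_tail_by_enumeration, naive_linkage_heights


def test_tail_probability_examples():
    assert hypergeometric_tail(0, 5, 4, 10) == 1.0
    # exhaustive: 6 of the C(10,5)=252 draws contain all 4 term genes
    assert hypergeometric_tail(4, 5, 4, 10) == pytest.approx(6 / 252)


def test_tail_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeometric_tail(5, 4, 4, 10)
    with pytest.raises(ValueError):
        hypergeometric_tail(2, 3, 11, 10)


def test_tail_matches_full_enumeration_small_universes():
    for N in range(2, 13):
        for n in range(0, N + 1):
            for K in range(0, N + 1):
                for k in range(0, min(n, K) + 1):
                    expected = hypergeom_tail_by_enumeration(k, n, K, N)
                    assert hypergeometric_tail(k, n, K, N) == pytest.approx(
                        expected, abs=1e-12
                    ), (k, n, K, N)


@pytest.fixture()
def flat_ontology():
    """50-gene universe, root plus three disjoint terms."""
    genes = [f"g{i}" for i in range(50)]
    sets = {
        "TA": genes[:8],
        "TB": genes[8:20],
        "TC": genes[20:30],
    }
    return Ontology(
        {"ROOT": [], "TA": ["ROOT"], "TB": ["ROOT"], "TC": ["ROOT"]},
        sets,
        universe=genes,
    )


def test_exact_term_neighborhood_is_top_hit(flat_ontology):
    table = enrich_set(set(flat_ontology.genes("TA")), flat_ontology, alpha=0.01)
    assert table.iloc[0]["term"] == "TA"
    assert bool(table.iloc[0]["accepted"])
    assert table.iloc[0]["p_value"] == table["p_value"].min()


def test_root_annotating_whole_universe_never_accepted():
    genes = [f"g{i}" for i in range(20)]
    ont = Ontology({"ROOT": [], "T1": ["ROOT"]},
                   {"ROOT": genes, "T1": genes[:5]}, universe=genes)
    table = enrich_set(set(genes[:5]), ont, alpha=0.01)
    root_row = table.set_index("term").loc["ROOT"]
    assert root_row["p_value"] == 1.0
    assert not bool(root_row["accepted"])


def test_empty_and_out_of_universe_neighborhoods(flat_ontology, caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        table = enrich_set([], flat_ontology)
    assert len(table) == 0
    table = enrich_set(["g0", "not_a_gene"], flat_ontology)
    assert (table["set_size"] == 1).all()  # the unknown gene was dropped


def test_acceptance_rate_matches_exact_null_level(rng):
    """Random neighborhoods: the empirical acceptance rate equals the exact
    attainable level of the discrete test (computed per term by summing the
    hypergeometric pmf), within CLT error over replicates."""
    genes = [f"g{i}" for i in range(400)]
    sets = {f"T{j}": list(rng.choice(genes, 80, replace=False)) for j in range(10)}
    ont = Ontology(
        {"ROOT": [], **{t: ["ROOT"] for t in sets}}, sets, universe=genes
    )
    alpha, n_hood, n_rep = 0.01, 40, 300
    # exact attainable level for K=80, n=40, N=400 at alpha
    N, K, n = 400, 80, n_hood
    ks = np.arange(0, min(K, n) + 1)
    tails = hypergeom.sf(ks - 1, N, K, n)
    attainable = float(hypergeom.pmf(ks[tails < alpha], N, K, n).sum())
    assert attainable <= alpha

    rates = []
    for _ in range(n_rep):
        hood = rng.choice(genes, n_hood, replace=False)
        table = enrich_set(hood, ont, alpha=alpha)
        accepted = int(table["accepted"].sum()) if len(table) else 0
        rates.append(accepted / 10)
    mean_rate = float(np.mean(rates))
    sem = float(np.std(rates, ddof=1) / math.sqrt(n_rep))
    assert abs(mean_rate - attainable) <= 4 * sem + 1e-4


def test_bh_correction_flag(flat_ontology):
    table = enrich_set(set(flat_ontology.genes("TA")), flat_ontology,
                       alpha=0.05, bh_correction=True)
    assert "p_adjusted" in table.columns
    assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()


def test_seed_term_matrix_counts(flat_ontology):
    tables = {
        "k1": enrich_set(set(flat_ontology.genes("TA")), flat_ontology),
        "k2": enrich_set(set(flat_ontology.genes("TB")), flat_ontology),
        "k3": enrich_set([], flat_ontology),
    }
    matrix = kinase_term_matrix(tables)
    assert (matrix.loc["k3"] == 0).all()  # empty table -> all-zero row
    # column sums equal per-term acceptance counts recomputed by direct scan
    for term in matrix.columns:
        direct = sum(
            int(((t["term"] == term) & t["accepted"]).any())
            for t in tables.values()
            if len(t)
        )
        assert matrix[term].sum() == direct


def test_filter_terms_thresholds(rng):
    m = pd.DataFrame((rng.random((20, 8)) < 0.3).astype(int),
                     index=[f"k{i}" for i in range(20)],
                     columns=[f"T{j}" for j in range(8)])
    for min_seeds in (1, 5, 21):
        kept = filter_terms(m, min_seeds)
        expected = [c for c in m.columns if m[c].sum() >= min_seeds]
        assert list(kept.columns) == expected
    assert filter_terms(m, 21).shape[1] == 0


@pytest.fixture()
def five_term_dag():
    """root(8 genes) -> A(4) -> {B(2), C(2)}; MICA(B, C) = A."""
    genes = [f"g{i}" for i in range(8)]
    return Ontology(
        {"root": [], "A": ["root"], "B": ["A"], "C": ["A"], "D": ["root"]},
        {"root": genes, "A": genes[:4], "B": genes[:2], "C": genes[2:4],
         "D": genes[4:7]},
        universe=genes,
    )


def test_information_content(five_term_dag):
    assert information_content("root", five_term_dag) == 0.0
    assert information_content("A", five_term_dag) == pytest.approx(math.log(2))


def test_information_content_monotone_root_to_leaf(tiny_ontology):
    ont = tiny_ontology
    for term in ont.terms:
        ic = information_content(term, ont)
        for parent in ont.parents(term):
            assert ic >= information_content(parent, ont) - 1e-12


def test_lin_similarity_hand_computed(five_term_dag):
    # sim(B, C) = 2*IC(A) / (IC(B) + IC(C)) = 2 ln2 / (2 ln4) = 0.5
    assert lin_similarity("B", "C", five_term_dag) == pytest.approx(0.5)
    assert lin_similarity("B", "B", five_term_dag) == 1.0
    assert lin_similarity("B", "D", five_term_dag) == 0.0  # only the root shared
    assert lin_similarity("root", "A", five_term_dag) == 0.0


def test_lin_similarity_symmetric_and_bounded(tiny_ontology):
    terms = list(tiny_ontology.terms)
    for t1, t2 in itertools.combinations(terms, 2):
        s = lin_similarity(t1, t2, tiny_ontology)
        assert 0.0 <= s <= 1.0
        assert s == lin_similarity(t2, t1, tiny_ontology)


def test_semantic_ordering_groups_siblings(five_term_dag):
    genes = [f"g{i}" for i in range(16)]
    ont = Ontology(
        {
            "root": [], "P1": ["root"], "P2": ["root"],
            "a1": ["P1"], "a2": ["P1"], "b1": ["P2"], "b2": ["P2"],
        },
        {
            "P1": genes[:8], "P2": genes[8:],
            "a1": genes[:3], "a2": genes[3:6],
            "b1": genes[8:11], "b2": genes[11:14],
        },
        universe=genes,
    )
    ordering = semantic_ordering(["a1", "b1", "a2", "b2"], ont)
    pos = {t: i for i, t in enumerate(ordering.ordered_terms)}
    assert abs(pos["a1"] - pos["a2"]) == 1
    assert abs(pos["b1"] - pos["b2"]) == 1


def test_duplicate_terms_order_adjacent(five_term_dag):
    ordering = semantic_ordering(["B", "C", "B", "D"], five_term_dag)
    first = ordering.ordered_terms.index("B")
    assert ordering.ordered_terms[first + 1] == "B"


def test_ward_ordering_heights_match_bruteforce(tiny_ontology):
    terms = sorted(tiny_ontology.terms)[:7]
    ordering = semantic_ordering(terms, tiny_ontology)
    dist = {
        (i, j): 1.0 - lin_similarity(terms[i], terms[j], tiny_ontology)
        for i, j in itertools.combinations(range(len(terms)), 2)
    }
    oracle = naive_linkage_heights(dist, len(terms), "ward")
    np.testing.assert_allclose(
        np.sort(ordering.linkage[:, 2]), np.sort(oracle), atol=1e-10
    )
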