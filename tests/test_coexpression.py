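"""Correlation graph gating and non-backtracking walk behavior."""
import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from kinact import (
    SimulationConfig,
    WalkConfig,
    marker_correlations,
    n_pairs,
    neighborhood_set,
    pairwise_correlation,
    random_walk_profile,
    simulate_expression,
)
from kinact.coexpression import (
    CorrelationGraph,
    _iter_walks,
    nearest_rank_quantile,
    valid_links,
)

from oracles import (
    nonbacktracking_reachable,
    nonbacktracking_visit_expectation,
)


def _graph_from_valid(valid):
    """CorrelationGraph with given link structure (r values irrelevant)."""
    genes = sorted(valid)
    corr = pd.DataFrame(np.nan, index=genes, columns=genes)
    for u, targets in valid.items():
        for v in targets:
            corr.loc[u, v] = 0.9
    return CorrelationGraph(corr, {g: tuple(sorted(valid[g])) for g in genes}, 0.999, 3)


def test_perfect_linear_relationships():
    x = np.arange(10.0)
    m = pd.DataFrame(
        {"s%d" % i: [x[i], 2 * x[i] + 1, -x[i]] for i in range(10)},
        index=["x", "y", "z"],
    )
    graph = pairwise_correlation(m, min_overlap=3)
    assert graph.corr.loc["x", "y"] == pytest.approx(1.0)
    assert graph.corr.loc["x", "z"] == pytest.approx(-1.0)


def test_pair_count_formula():
    assert n_pairs(2) == 1
    assert n_pairs(5) == 10
    assert n_pairs(11906) == 70870465  # ~70.9 million


def test_correlation_symmetric_bounded_with_nan_diagonal(tiny_dataset):
    matrix, _, _ = tiny_dataset
    graph = pairwise_correlation(matrix, min_overlap=10)
    values = graph.corr.to_numpy()
    assert np.isnan(np.diag(values)).all()
    off = values[~np.isnan(values)]
    assert ((off >= -1 - 1e-12) & (off <= 1 + 1e-12)).all()
    pd.testing.assert_frame_equal(graph.corr, graph.corr.T)


def test_insufficient_overlap_yields_missing_correlation(rng):
    m = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"])
    m.iloc[0, :15] = np.nan  # a and b share only 5 samples
    graph = pairwise_correlation(m, min_overlap=10)
    assert np.isnan(graph.corr.loc["a", "b"])
    assert not np.isnan(graph.corr.loc["b", "c"])


def test_zero_variance_gene_has_no_correlations(rng):
    m = pd.DataFrame(rng.normal(size=(3, 30)), index=["a", "b", "c"])
    m.loc["a"] = 1.0
    graph = pairwise_correlation(m, min_overlap=5)
    assert np.isnan(graph.corr.loc["a", "b"]) and np.isnan(graph.corr.loc["a", "c"])
    assert graph.valid["a"] == ()


def test_valid_links_match_sort_threshold_oracle(rng):
    values = rng.normal(size=1000)
    corr = pd.DataFrame(np.nan, index=["u"] + [f"v{i}" for i in range(1000)],
                        columns=["u"] + [f"v{i}" for i in range(1000)])
    corr.loc["u", corr.columns[1:]] = values
    links = valid_links(corr, 0.999)["u"]
    # oracle: sort, nearest-rank threshold, keep everything at/above it
    thr = np.sort(values)[int(np.ceil(0.999 * 1000)) - 1]
    expected = {f"v{i}" for i, v in enumerate(values) if v >= thr}
    assert set(links) == expected
    assert len(links) >= 1


def test_percentile_zero_keeps_every_link(rng):
    m = pd.DataFrame(rng.normal(size=(6, 40)), index=list("abcdef"))
    graph = pairwise_correlation(m, min_overlap=5, percentile=0.0)
    for g in "abcdef":
        assert len(graph.valid[g]) == 5


def test_validity_can_be_asymmetric():
    """u's best link is v, while r(u, v) ranks low among v's correlations."""
    genes = ["u", "v", "w", "x"]
    corr = pd.DataFrame(np.nan, index=genes, columns=genes)

    def set_r(a, b, r):
        corr.loc[a, b] = corr.loc[b, a] = r

    set_r("u", "v", 0.5)   # u's maximum ...
    set_r("u", "w", 0.1)
    set_r("u", "x", 0.0)
    set_r("v", "w", 0.9)   # ... but v correlates better with w and x
    set_r("v", "x", 0.8)
    set_r("w", "x", 0.2)
    links = valid_links(corr, 0.999)
    assert links["u"] == ("v",)
    assert "u" not in links["v"]  # direct rank inspection: u is v's 3rd of 3


def test_dead_end_chain_profile():
    graph = _graph_from_valid({"s": ("t",), "t": ("s",)})
    profile = random_walk_profile(graph, "s", WalkConfig(500, 5, 1))
    assert profile.counts == {"t": 500}
    assert profile.terminated_early == 500


def test_forced_path_visits_every_node_once():
    graph = _graph_from_valid(
        {"s": ("a",), "a": ("b",), "b": ("c",), "c": ("d",), "d": ("e",), "e": ()}
    )
    profile = random_walk_profile(graph, "s", WalkConfig(200, 5, 2))
    assert profile.counts == {g: 200 for g in "abcde"}
    assert profile.terminated_early == 0


def test_isolated_seed_gives_empty_profile():
    graph = _graph_from_valid({"s": (), "t": ("s",)})
    profile = random_walk_profile(graph, "s", WalkConfig(100, 5, 3))
    assert profile.counts == {}
    assert profile.terminated_early == 100


def test_profile_support_matches_exhaustive_path_enumeration(rng):
    for trial in range(4):
        nodes = [f"n{i}" for i in range(10)]
        valid = {
            u: tuple(
                sorted(rng.choice([v for v in nodes if v != u], size=3, replace=False))
            )
            if rng.random() > 0.2
            else ()
            for u in nodes
        }
        graph = _graph_from_valid(valid)
        profile = random_walk_profile(graph, "n0", WalkConfig(10000, 5, 50 + trial))
        expected = nonbacktracking_reachable(valid, "n0", 5)
        assert profile.support() == expected


def test_walks_never_backtrack_and_respect_length(rng):
    nodes = [f"n{i}" for i in range(8)]
    valid = {
        u: tuple(sorted(rng.choice([v for v in nodes if v != u], 3, replace=False)))
        for u in nodes
    }
    graph = _graph_from_valid(valid)
    cfg = WalkConfig(300, 5, 9)
    for path in _iter_walks(graph, "n0", cfg):
        assert len(path) <= cfg.walk_length
        seq = ["n0"] + path
        for i in range(2, len(seq)):
            assert seq[i] != seq[i - 2]  # no immediate backtracking
        for i in range(1, len(seq)):
            assert seq[i] in valid[seq[i - 1]]  # only valid links


def test_profile_reproducible_under_fixed_seed(tiny_dataset):
    matrix, _, _ = tiny_dataset
    graph = pairwise_correlation(matrix, min_overlap=10, percentile=0.9)
    seed_gene = graph.genes[0]
    p1 = random_walk_profile(graph, seed_gene, WalkConfig(200, 5, 42))
    p2 = random_walk_profile(graph, seed_gene, WalkConfig(200, 5, 42))
    assert p1.counts == p2.counts and p1.terminated_early == p2.terminated_early


def test_visit_frequencies_converge_to_exact_distribution(rng):
    """Relative visit frequencies approach the exhaustive-enumeration
    expectation of the non-backtracking walk (TV <= 0.02 at 50k walks)."""
    nodes = list("abcdef")
    valid = {
        "a": ("b", "c"),
        "b": ("a", "d"),
        "c": ("d", "e"),
        "d": ("b", "f"),
        "e": ("a",),
        "f": ("c", "e"),
    }
    graph = _graph_from_valid(valid)
    profile = random_walk_profile(graph, "a", WalkConfig(50000, 5, 11))
    expected = nonbacktracking_visit_expectation(valid, "a", 5)
    total_obs = sum(profile.counts.values())
    total_exp = sum(expected.values())
    tv = 0.5 * sum(
        abs(profile.counts.get(g, 0) / total_obs - expected.get(g, 0) / total_exp)
        for g in set(profile.counts) | set(expected)
    )
    assert tv <= 0.02


def test_neighborhood_thresholding():
    profile_counts = {"a": 5, "b": 2, "c": 1}
    from kinact.coexpression import VisitProfile

    profile = VisitProfile("s", profile_counts, 10, 0)
    assert neighborhood_set(profile, 1) == {"a", "b", "c"}
    assert neighborhood_set(profile, 2) == {"a", "b"}
    assert neighborhood_set(profile, 99) == frozenset()


def test_neighborhood_enriched_for_own_module(rng):
    """A module member's walk neighborhood contains far more of its own
    module than a uniform draw of the same size would."""
    cfg = SimulationConfig(
        n_genes=300, n_tissues=80, samples_per_tissue=5, n_modules=3,
        module_size=15, module_factor_sd=3.0, missing_rate=0.0, n_terms=10, seed=4,
    )
    matrix, _, truth = simulate_expression(cfg)
    graph = pairwise_correlation(matrix, min_overlap=30, percentile=0.999)
    seed_gene = "g0000"
    profile = random_walk_profile(graph, seed_gene, WalkConfig(500, 5, 21))
    hood = neighborhood_set(profile, 2)
    assert hood
    own = {g for g, m in truth.module_membership.items() if m == 0}
    overlap = len(hood & own)
    expected_uniform = len(hood) * len(own) / cfg.n_genes
    assert overlap > 4 * expected_uniform
    assert overlap / len(hood) > 0.5


def test_marker_correlation_examples(rng, tiny_dataset):
    matrix, _, truth = tiny_dataset
    markers = [truth.marker_genes[m] for m in sorted(truth.marker_genes)]
    table = marker_correlations(matrix, [markers[0]], markers, min_overlap=10)
    assert table.loc[markers[0], markers[0]] == pytest.approx(1.0)
    with pytest.raises(KeyError):
        marker_correlations(matrix, ["nope"], markers)


def test_independent_marker_correlations_are_small(rng):
    m = pd.DataFrame(rng.normal(size=(21, 1000)),
                     index=["t"] + [f"mk{i}" for i in range(20)])
    table = marker_correlations(m, ["t"], [f"mk{i}" for i in range(20)])
    assert (table.abs() < 0.1).all().all()


def test_module_members_track_their_own_marker():
    cfg = SimulationConfig(
        n_genes=60, n_tissues=20, samples_per_tissue=10, n_modules=3,
        module_size=8, module_factor_sd=3.0, missing_rate=0.0, n_terms=10, seed=6,
    )
    matrix, _, truth = simulate_expression(cfg)
    markers = [truth.marker_genes[m] for m in sorted(truth.marker_genes)]
    members = [g for g, m in truth.module_membership.items() if g not in markers]
    table = marker_correlations(matrix, members, markers, min_overlap=10)
    for g in members:
        own = truth.marker_genes[truth.module_membership[g]]
        others = [mk for mk in markers if mk != own]
        assert table.loc[g, own] > table.loc[g, others].max()
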