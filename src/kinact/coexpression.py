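"""All-vs-all Pearson correlation graph and non-backtracking random walks.

Correlations are computed over pairwise-complete observations; pairs with
fewer than ``min_overlap`` shared non-missing samples carry no correlation.
Each gene then gates its own links: a link u -> v is *valid* iff r(u, v)
reaches the empirical top-percentile (0.999 by default, nearest-rank, on
signed values) of u's available correlations — validity is therefore
directed and may be asymmetric.  Random walks start at a seed gene, choose
uniformly among the current node's valid links excluding the immediately
previous node, and terminate early at dead ends; the multiplicity-counted
visit profile over many walks defines the seed's co-expression neighborhood.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import WalkConfig

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationGraph",
    "VisitProfile",
    "n_pairs",
    "pairwise_correlation",
    "valid_links",
    "nearest_rank_quantile",
    "random_walk_profile",
    "neighborhood_set",
    "marker_correlations",
]


@dataclass
class CorrelationGraph:
    """Symmetric correlation table plus per-gene directed valid-link sets."""

    corr: pd.DataFrame  # genes x genes, NaN where unavailable; NaN diagonal
    valid: Dict[str, Tuple[str, ...]]  # source gene -> sorted valid targets
    percentile: float
    min_overlap: int

    @property
    def genes(self) -> List[str]:
        return list(self.corr.index)


@dataclass
class VisitProfile:
    """Visit counts (with multiplicity, seed excluded) across all walks."""

    seed: str
    counts: Dict[str, int]
    n_walks: int
    terminated_early: int

    def support(self) -> FrozenSet[str]:
        return frozenset(g for g, c in self.counts.items() if c > 0)


def n_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n(n-1)/2."""
    return n_genes * (n_genes - 1) // 2


def pairwise_correlation(
    matrix: pd.DataFrame,
    min_overlap: int = 30,
    percentile: float = 0.999,
) -> CorrelationGraph:
    """Pearson correlations between all gene pairs plus valid-link gates.

    ``matrix`` is genes x samples with NaN for missing values.  Pairs with
    fewer than ``min_overlap`` shared non-missing samples, and pairs where
    a gene has zero variance on the shared support, are recorded as missing.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    corr = matrix.T.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.to_numpy(), np.nan)
    n_missing = int(np.isnan(corr.to_numpy()).sum() - len(corr))
    if n_missing:
        log.info(
            "%d ordered pairs carry no correlation (overlap < %d or zero variance)",
            n_missing,
            min_overlap,
        )
    valid = valid_links(corr, percentile)
    return CorrelationGraph(corr, valid, percentile, min_overlap)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile: the ceil(q*n)-th smallest value
    (the minimum for q = 0)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("quantile of an empty set")
    rank = max(1, math.ceil(q * n))
    return float(values[rank - 1])


def valid_links(corr: pd.DataFrame, percentile: float = 0.999) -> Dict[str, Tuple[str, ...]]:
    """Per-source-gene valid-link sets.

    For each gene u the threshold is the nearest-rank quantile at
    ``percentile`` of u's available (signed) correlations; links with
    r >= threshold are valid.  At least one link is retained whenever any
    correlation exists; genes with none are isolated (empty tuple).
    """
    out: Dict[str, Tuple[str, ...]] = {}
    n_isolated = 0
    values = corr.to_numpy()
    index = corr.index
    cols = np.asarray(corr.columns)
    for i, u in enumerate(index):
        row = values[i]
        avail = ~np.isnan(row)
        if not avail.any():
            out[u] = ()
            n_isolated += 1
            continue
        thr = nearest_rank_quantile(row[avail], percentile)
        out[u] = tuple(sorted(cols[avail & (row >= thr)]))
    if n_isolated:
        log.warning("%d genes have no computed correlations (isolated)", n_isolated)
    return out


def _iter_walks(
    graph: CorrelationGraph, seed_gene: str, config: WalkConfig
) -> Iterator[List[str]]:
    """Yield each walk as the list of visited nodes after the seed.

    Exposed for tests that assert the per-step contracts (never more than
    ``walk_length`` steps, never an immediate backtrack).
    """
    if seed_gene not in graph.corr.index:
        raise KeyError(f"seed gene {seed_gene!r} not in graph")
    rng = np.random.default_rng(config.rng_seed)
    valid = graph.valid
    for _ in range(config.n_walks):
        path: List[str] = []
        prev: Optional[str] = None
        cur = seed_gene
        for _step in range(config.walk_length):
            options = valid[cur]
            if prev is not None and prev in options:
                options = tuple(t for t in options if t != prev)
            if not options:
                break
            nxt = options[rng.integers(len(options))]
            path.append(nxt)
            prev, cur = cur, nxt
        yield path


def random_walk_profile(
    graph: CorrelationGraph, seed_gene: str, config: Optional[WalkConfig] = None
) -> VisitProfile:
    """Visit-frequency profile of non-backtracking walks from a seed gene.

    Every visited node increments the profile with multiplicity; visits to
    the seed itself are not counted.  Walks with no permissible move
    terminate early and are tallied in ``terminated_early``.
    """
    config = config or WalkConfig()
    if not graph.valid.get(seed_gene, ()):
        log.warning("seed gene %s is isolated; empty profile", seed_gene)
    counts: Counter = Counter()
    early = 0
    for path in _iter_walks(graph, seed_gene, config):
        if len(path) < config.walk_length:
            early += 1
        for node in path:
            if node != seed_gene:
                counts[node] += 1
    return VisitProfile(seed_gene, dict(counts), config.n_walks, early)


def neighborhood_set(profile: VisitProfile, min_visits: int = 2) -> FrozenSet[str]:
    """Genes visited at least ``min_visits`` times (seed excluded)."""
    return frozenset(g for g, c in profile.counts.items() if c >= min_visits)


def marker_correlations(
    matrix: pd.DataFrame,
    target_genes: Iterable[str],
    marker_genes: Sequence[str],
    min_overlap: int = 30,
) -> pd.DataFrame:
    """Pearson r between every target and every marker gene
    (pairwise-complete observations); targets as rows, markers as columns."""
    targets = list(target_genes)
    markers = list(marker_genes)
    missing = [g for g in targets + markers if g not in matrix.index]
    if missing:
        raise KeyError(f"genes not in matrix, e.g. {missing[:3]}")
    both = list(dict.fromkeys(targets + markers))
    corr = matrix.loc[both].T.corr(method="pearson", min_periods=min_overlap)
    return corr.loc[targets, markers]
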