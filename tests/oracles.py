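"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own code paths: plain-Python
enumeration, naive O(n^3) agglomeration and exhaustive DAG traversal.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Dict, List, Sequence, Set, Tuple


def entropy_bits(labels) -> float:
    counts = Counter(labels)
    n = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def exhaustive_max_entropy_window(
    values: Sequence[float],
    labels: Sequence,
    window_frac: float = 0.05,
    step_frac: float = 0.01,
) -> Tuple[float, float]:
    """(midpoint, entropy) of the max-entropy window by plain enumeration;
    ties broken towards the highest midpoint."""
    pairs = [(v, l) for v, l in zip(values, labels) if v == v]  # drop NaN
    vmax = max(v for v, _ in pairs)
    width = window_frac * vmax
    step = step_frac * vmax
    n_steps = int(math.floor(1.0 / step_frac + 1e-9))
    best = None
    for i in range(n_steps + 1):
        lo = i * step
        window = [l for v, l in pairs if lo <= v < lo + width]
        if not window:
            continue
        h = entropy_bits(window)
        mid = lo + width / 2.0
        if best is None or h > best[1] or (h == best[1] and mid > best[0]):
            best = (mid, h)
    return best


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws from the universe."""
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def jaccard_binary(u: Sequence[int], v: Sequence[int]) -> float:
    either = sum(1 for a, b in zip(u, v) if a or b)
    if either == 0:
        return 0.0
    diff = sum(1 for a, b in zip(u, v) if bool(a) != bool(b))
    return diff / either


def naive_linkage_heights(dist: Dict[Tuple[int, int], float], n: int, method: str) -> List[float]:
    """Merge heights of naive agglomerative clustering (complete or Ward).

    Ward follows the Lance-Williams recurrence on squared distances, matching
    what scipy computes from a condensed distance matrix.
    """
    d = {}
    for (i, j), v in dist.items():
        d[frozenset((i, j))] = v
    clusters: Dict[int, Set[int]] = {i: {i} for i in range(n)}
    next_id = n
    heights = []
    while len(clusters) > 1:
        (a, b), h = min(
            (
                ((a, b), d[frozenset((a, b))])
                for a, b in itertools.combinations(sorted(clusters), 2)
            ),
            key=lambda kv: (kv[1], kv[0]),
        )
        heights.append(h)
        merged = clusters[a] | clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        dab = d[frozenset((a, b))]
        for c in clusters:
            if c in (a, b):
                continue
            dac = d[frozenset((a, c))]
            dbc = d[frozenset((b, c))]
            if method == "complete":
                dnew = max(dac, dbc)
            elif method == "ward":
                nc = len(clusters[c])
                dnew = math.sqrt(
                    (
                        (na + nc) * dac**2
                        + (nb + nc) * dbc**2
                        - nc * dab**2
                    )
                    / (na + nb + nc)
                )
            else:
                raise ValueError(method)
            d[frozenset((next_id, c))] = dnew
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return heights


def nonbacktracking_reachable(
    valid: Dict[str, Tuple[str, ...]], seed: str, max_len: int
) -> Set[str]:
    """Nodes reachable from ``seed`` by >= 1 valid non-backtracking path of
    length <= ``max_len``, by exhaustive depth-first path enumeration."""
    reached: Set[str] = set()

    def walk(prev, cur, depth):
        if depth == max_len:
            return
        for nxt in valid.get(cur, ()):
            if nxt == prev:
                continue
            reached.add(nxt)
            walk(cur, nxt, depth + 1)

    walk(None, seed, 0)
    reached.discard(seed)
    return reached


def nonbacktracking_visit_expectation(
    valid: Dict[str, Tuple[str, ...]], seed: str, max_len: int
) -> Dict[str, float]:
    """Expected visit counts (seed excluded) of one non-backtracking walk,
    by enumerating all paths with their exact probabilities."""
    expected: Dict[str, float] = {}

    def walk(prev, cur, depth, prob):
        if depth == max_len:
            return
        options = [t for t in valid.get(cur, ()) if t != prev]
        if not options:
            return
        for nxt in options:
            p = prob / len(options)
            if nxt != seed:
                expected[nxt] = expected.get(nxt, 0.0) + p
            walk(cur, nxt, depth + 1, p)

    walk(None, seed, 0, 1.0)
    return expected


def all_ancestors_by_traversal(parents: Dict[str, List[str]], term: str) -> Set[str]:
    """Ancestors of a term by exhaustive upward traversal (excluding self)."""
    seen: Set[str] = set()
    frontier = list(parents.get(term, []))
    while frontier:
        t = frontier.pop()
        if t in seen:
            continue
        seen.add(t)
        frontier.extend(parents.get(t, []))
    return seen
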