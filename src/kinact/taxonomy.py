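"""Clustering of the binary activity matrix and healthy-vs-malignant calls.

Both axes of the genes x tissues activity matrix are clustered with the
asymmetric-binary (Jaccard) distance — joint inactivity is uninformative and
0/0 matches are ignored — under complete or Ward linkage.  Cutting the
tissue tree recovers tissue groups whose composition is summarized as
majority-class purity; gene-group-by-tissue-group activity shares reproduce
the group-composition percentages of the source analysis.  Gains and losses
of activity between a paired healthy and malignant tissue are plain set
differences of the two binary columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GroupAssignment",
    "GainLossReport",
    "binary_distance",
    "cluster_binary",
    "cut_groups",
    "group_purity",
    "group_activity_share",
    "gain_loss",
    "changed_fraction",
]


@dataclass
class GroupAssignment:
    """An agglomerative hierarchy over one axis of a matrix."""

    items: List[str]
    linkage: np.ndarray  # scipy linkage matrix
    axis: str
    method: str

    def cut(self, k: int) -> Dict[str, int]:
        return cut_groups(self, k)


@dataclass
class GainLossReport:
    """Genes whose activity differs between a reference and a comparison tissue."""

    reference_tissue: str
    comparison_tissue: str
    gained: FrozenSet[str]  # active in comparison, not in reference
    lost: FrozenSet[str]  # active in reference, not in comparison
    n_total_genes: int

    def __post_init__(self) -> None:
        if self.gained & self.lost:
            raise ValueError("gained and lost gene sets must be disjoint")


def binary_distance(u: Sequence[int], v: Sequence[int]) -> float:
    """Asymmetric-binary (Jaccard) distance between two 0/1 vectors.

    (positions where exactly one is 1) / (positions where at least one is 1);
    0-0 matches are ignored.  Two all-zero vectors get distance 0 so that
    identical profiles always co-cluster.
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    either = int(np.count_nonzero(u | v))
    if either == 0:
        return 0.0
    both = int(np.count_nonzero(u & v))
    return (either - both) / either


def cluster_binary(
    activity: pd.DataFrame, axis: str = "tissues", method: str = "complete"
) -> GroupAssignment:
    """Hierarchical clustering of the activity matrix along one axis.

    ``axis`` selects gene rows (``"genes"``) or tissue columns
    (``"tissues"``); ``method`` is ``"complete"`` or ``"ward"``.  The result
    is deterministic for a fixed input ordering.
    """
    if axis == "tissues":
        data = activity.T
    elif axis == "genes":
        data = activity
    else:
        raise ValueError(f"axis must be 'genes' or 'tissues', got {axis!r}")
    if method not in ("complete", "ward"):
        raise ValueError(f"linkage must be 'complete' or 'ward', got {method!r}")
    if data.shape[0] < 2:
        raise ValueError(f"need at least 2 items on axis {axis!r}")
    dist = pdist(data.to_numpy(dtype=bool), metric="jaccard")
    Z = hierarchy.linkage(dist, method=method)
    return GroupAssignment(list(data.index), Z, axis, method)


def cut_groups(assignment: GroupAssignment, k: int) -> Dict[str, int]:
    """Cut the tree into ``k`` flat groups; returns item -> group id (1..k)."""
    flat = hierarchy.fcluster(assignment.linkage, t=k, criterion="maxclust")
    return dict(zip(assignment.items, (int(c) for c in flat)))


def group_purity(groups: Dict[str, int], labels: Dict[str, str]) -> pd.DataFrame:
    """Majority-class purity of each group.

    Returns a DataFrame indexed by group id with columns
    ``n, majority_class, purity`` where purity is the fraction of members
    carrying the group's most frequent class label.
    """
    unlabelled = [i for i in groups if i not in labels]
    if unlabelled:
        raise KeyError(f"items without class label, e.g. {unlabelled[:3]}")
    df = pd.DataFrame(
        {"group": [groups[i] for i in groups], "label": [labels[i] for i in groups]}
    )
    rows = []
    for gid, sub in df.groupby("group"):
        counts = sub["label"].value_counts()
        rows.append(
            {
                "group": gid,
                "n": len(sub),
                "majority_class": counts.index[0],
                "purity": counts.iloc[0] / len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def group_activity_share(
    activity: pd.DataFrame, gene_group: Iterable[str], tissue_group: Iterable[str]
) -> float:
    """Mean over genes of the fraction of the tissue group where each gene is
    active, as a percentage."""
    genes = list(gene_group)
    tissues = list(tissue_group)
    if not genes or not tissues:
        raise ValueError("gene_group and tissue_group must be non-empty")
    sub = activity.loc[genes, tissues]
    return float(sub.mean(axis=1).mean() * 100.0)


def gain_loss(
    activity: pd.DataFrame, reference: str, comparison: str
) -> GainLossReport:
    """Genes gaining / losing activity between two tissues.

    gained: active in ``comparison`` but not ``reference``;
    lost: active in ``reference`` but not ``comparison``.
    """
    for t in (reference, comparison):
        if t not in activity.columns:
            raise KeyError(f"unknown tissue {t!r}")
    ref = activity[reference].astype(bool)
    cmp_ = activity[comparison].astype(bool)
    gained = frozenset(activity.index[cmp_ & ~ref])
    lost = frozenset(activity.index[ref & ~cmp_])
    return GainLossReport(reference, comparison, gained, lost, len(activity.index))


def changed_fraction(report: GainLossReport) -> float:
    """Percentage of all genes gained or lost, rounded to one decimal."""
    if report.n_total_genes <= 0:
        raise ValueError("n_total_genes must be > 0")
    pct = 100.0 * (len(report.gained) + len(report.lost)) / report.n_total_genes
    return round(pct, 1)
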