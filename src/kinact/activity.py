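"""Entropy-window background thresholds and binary activity calls.

Each gene's background cutoff is found by sliding a window (width 5% of the
gene's maximum expression) from zero to the maximum over a reference sample
set, computing the Shannon entropy of the tissue labels falling in each
window, and recording the midpoint of the maximum-entropy window.  Twice the
sample SD of the values strictly below that midpoint is added to reach the
cutoff.  A gene is then called transcriptionally active in a tissue when its
median expression there is strictly greater than the cutoff.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ActivityParams
from .errors import DegenerateGeneError, EmptyWindowError

log = logging.getLogger(__name__)

__all__ = [
    "EntropyProfile",
    "ActivityThreshold",
    "label_entropy",
    "entropy_profile",
    "background_cutoff",
    "compute_thresholds",
    "call_activity",
]


@dataclass
class EntropyProfile:
    """Label entropy over the sliding windows of one gene.

    ``window_midpoints`` are strictly increasing; empty windows carry no
    entry, so the two arrays always have equal length.
    """

    window_midpoints: np.ndarray
    entropies: np.ndarray  # bits
    window_width: float

    def __post_init__(self) -> None:
        self.window_midpoints = np.asarray(self.window_midpoints, dtype=float)
        self.entropies = np.asarray(self.entropies, dtype=float)
        if self.window_midpoints.shape != self.entropies.shape:
            raise ValueError("midpoints and entropies must have equal length")
        if np.any(np.diff(self.window_midpoints) <= 0):
            raise ValueError("window midpoints must be strictly increasing")
        if np.any(self.entropies < 0):
            raise ValueError("entropies must be >= 0")


@dataclass
class ActivityThreshold:
    """Per-gene background cutoff.

    ``cutoff = midpoint + sd_multiplier * sd_below``; when fewer than two
    values lie strictly below the midpoint the SD is undefined, the cutoff
    falls back to the midpoint and ``degenerate`` is set.
    """

    gene: str
    midpoint: float
    sd_below: float
    cutoff: float
    degenerate: bool = False


def label_entropy(labels: Sequence) -> float:
    """Shannon entropy (bits) of a multiset of class labels.

    0 for a single class, log2(k) for k equally frequent classes.
    """
    counts = np.asarray(list(Counter(labels).values()), dtype=float)
    if counts.size == 0:
        raise EmptyWindowError("label entropy of an empty window is undefined")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_profile(
    values: Sequence[float],
    labels: Sequence,
    window_frac: float = 0.05,
    step_frac: float = 0.01,
) -> EntropyProfile:
    """Sliding-window label-entropy profile of one gene.

    Windows are half-open intervals ``[lo, lo + window_frac * max)`` with
    ``lo`` on a grid from 0 to the maximum value in steps of
    ``step_frac * max``.  Missing values (NaN) are excluded; empty windows
    are skipped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    if values.size < 2:
        raise DegenerateGeneError("need at least 2 non-missing values")
    vmax = float(values.max())
    if vmax <= 0:
        raise DegenerateGeneError("maximum expression must be > 0")

    width = window_frac * vmax
    step = step_frac * vmax
    n_steps = int(math.floor(1.0 / step_frac + 1e-9))
    # Sort once; each window is a contiguous slice of the sorted values.
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    sorted_labels = labels[order]
    # integer-code labels once for cheap per-window entropy
    _, codes = np.unique(sorted_labels, return_inverse=True)

    midpoints, entropies = [], []
    for i in range(n_steps + 1):
        lo = i * step
        a = np.searchsorted(sorted_vals, lo, side="left")
        b = np.searchsorted(sorted_vals, lo + width, side="left")
        if b <= a:
            continue
        counts = np.bincount(codes[a:b]).astype(float)
        counts = counts[counts > 0]
        p = counts / counts.sum()
        midpoints.append(lo + width / 2.0)
        entropies.append(float(-(p * np.log2(p)).sum()))
    return EntropyProfile(np.array(midpoints), np.array(entropies), width)


def background_cutoff(
    profile: EntropyProfile,
    values: Sequence[float],
    gene: str = "",
    sd_multiplier: float = 2.0,
) -> ActivityThreshold:
    """Background cutoff from the maximum-entropy window.

    Ties on the maximum entropy are broken towards the highest midpoint,
    which yields the most conservative (highest) cutoff.  ``sd_below`` is
    the sample SD (n-1 denominator) of the non-missing values strictly
    below the midpoint.
    """
    if profile.window_midpoints.size == 0:
        raise DegenerateGeneError("entropy profile is empty")
    hmax = profile.entropies.max()
    tied = profile.window_midpoints[profile.entropies == hmax]
    midpoint = float(tied.max())

    values = np.asarray(values, dtype=float)
    below = values[~np.isnan(values) & (values < midpoint)]
    if below.size < 2:
        return ActivityThreshold(gene, midpoint, 0.0, midpoint, degenerate=True)
    sd = float(below.std(ddof=1))
    return ActivityThreshold(gene, midpoint, sd, midpoint + sd_multiplier * sd)


def compute_thresholds(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    params: Optional[ActivityParams] = None,
) -> pd.DataFrame:
    """Per-gene background thresholds over the reference sample set.

    The reference set is the samples whose ``state`` equals
    ``params.reference_state`` (healthy by default); the entropy labels are
    their tissue types.  Genes with no usable reference data are flagged
    ``no_data`` with a NaN cutoff (their activity calls are all 0).

    Returns a DataFrame indexed by gene with columns
    ``midpoint, sd_below, cutoff, degenerate``.
    """
    params = params or ActivityParams()
    ann = annotation.set_index("sample_id")
    ref_samples = ann.index[ann["state"] == params.reference_state]
    ref_samples = [s for s in matrix.columns if s in set(ref_samples)]
    if not ref_samples:
        raise ValueError(
            f"no samples with state == {params.reference_state!r} in the annotation"
        )
    labels = ann.loc[ref_samples, "tissue_type"].to_numpy()
    sub = matrix[ref_samples]

    rows = []
    n_degenerate = 0
    for gene, values in sub.iterrows():
        vals = values.to_numpy(dtype=float)
        try:
            prof = entropy_profile(vals, labels, params.window_frac, params.step_frac)
        except DegenerateGeneError:
            n_degenerate += 1
            rows.append((gene, np.nan, np.nan, np.nan, "no_data"))
            continue
        thr = background_cutoff(prof, vals, gene, params.sd_multiplier)
        rows.append(
            (
                gene,
                thr.midpoint,
                thr.sd_below,
                thr.cutoff,
                "sd_undefined" if thr.degenerate else "",
            )
        )
    if n_degenerate:
        log.warning("%d genes had no usable reference data", n_degenerate)
    out = pd.DataFrame(
        rows, columns=["gene", "midpoint", "sd_below", "cutoff", "degenerate"]
    ).set_index("gene")
    return out


def call_activity(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: pd.DataFrame,
) -> pd.DataFrame:
    """Binary genes x tissues activity calls.

    A gene is active in a tissue iff the median of its non-missing values
    there is strictly greater than its cutoff.  Tissues with no data for a
    gene (or genes with a NaN cutoff) are called 0 and counted in a log
    message.
    """
    missing_thr = [g for g in matrix.index if g not in thresholds.index]
    if missing_thr:
        raise KeyError(
            f"{len(missing_thr)} genes lack thresholds, e.g. {missing_thr[:3]}"
        )
    ann = annotation.set_index("sample_id")
    unlabelled = [s for s in matrix.columns if s not in ann.index]
    if unlabelled:
        raise KeyError(
            f"{len(unlabelled)} samples lack annotation, e.g. {unlabelled[:3]}"
        )
    tissue_of = ann.loc[matrix.columns, "tissue_type"]
    # tissues x genes table of per-tissue medians over non-missing values
    medians = matrix.T.groupby(tissue_of.to_numpy()).median()
    cutoffs = thresholds.loc[matrix.index, "cutoff"]
    n_empty = int(medians.isna().to_numpy().sum())
    if n_empty:
        log.warning(
            "%d gene/tissue cells had no non-missing values; called inactive", n_empty
        )
    calls = medians.gt(cutoffs, axis=1).T.astype(np.int8)
    calls.index.name = "gene"
    calls.columns.name = "tissue"
    return calls
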