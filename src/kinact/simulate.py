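"""Synthetic multi-tissue expression generator with planted ground truth.

The generator emulates the statistical structure this analysis needs from a
large curated expression corpus, at desk scale:

* per-gene bimodal expression: a clipped-Gaussian background shared by all
  tissues where the gene is inactive, plus an active component shifted
  upwards by a fixed number of background SDs in a subset of tissues;
* many tissue classes with replicate samples, split into paired healthy and
  malignant conditions (``healthy_07`` pairs with ``malignant_07``);
* correlated gene modules driven by a shared per-sample latent factor,
  strong enough to pass a per-gene top-percentile correlation gate;
* completely-at-random missing values;
* a small rooted term DAG whose designated terms annotate the module genes.

Every quantity the downstream stages are supposed to recover is returned as
:class:`SyntheticTruth`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .ontology import Ontology

__all__ = ["SyntheticTruth", "simulate_expression", "simulate_ontology"]


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated dataset."""

    true_activity: pd.DataFrame  # genes x tissues, int {0,1}
    module_membership: Dict[str, int]  # gene -> module id (module genes only)
    term_annotations: Dict[str, FrozenSet[str]]  # term -> annotated genes (closed)
    marker_genes: Dict[int, str]  # module -> designated marker gene
    module_terms: Dict[int, str]  # module -> its designated ontology term


def _gene_ids(n: int) -> List[str]:
    return [f"g{i:04d}" for i in range(n)]


def _tissue_names(n_tissues: int) -> List[str]:
    n_healthy = (n_tissues + 1) // 2
    names = [f"healthy_{i:02d}" for i in range(n_healthy)]
    names += [f"malignant_{i:02d}" for i in range(n_tissues - n_healthy)]
    return names


def _module_of(config: SimulationConfig) -> Dict[str, int]:
    genes = _gene_ids(config.n_genes)
    membership = {}
    for m in range(config.n_modules):
        for g in genes[m * config.module_size : (m + 1) * config.module_size]:
            membership[g] = m
    return membership


def _term_scheme(
    config: SimulationConfig,
) -> Tuple[Dict[str, List[str]], Dict[str, List[str]], Dict[int, str], Dict[str, str]]:
    """Deterministic term DAG layout shared by the expression and ontology
    generators: a root, one designated term per module, and filler terms
    chained below the module terms, each annotating the first half of its
    parent's genes."""
    genes = _gene_ids(config.n_genes)
    module_genes = {
        m: genes[m * config.module_size : (m + 1) * config.module_size]
        for m in range(config.n_modules)
    }
    root = "T000"
    parents: Dict[str, List[str]] = {root: []}
    annotations: Dict[str, List[str]] = {root: []}
    names: Dict[str, str] = {root: "biological process (root)"}
    module_terms: Dict[int, str] = {}
    chain_tail: Dict[int, Tuple[str, List[str]]] = {}
    for m in range(config.n_modules):
        term = f"T{m + 1:03d}"
        parents[term] = [root]
        annotations[term] = list(module_genes[m])
        names[term] = f"module {m} process"
        module_terms[m] = term
        chain_tail[m] = (term, list(module_genes[m]))
    for i in range(config.n_modules + 1, config.n_terms):
        term = f"T{i:03d}"
        m = (i - config.n_modules - 1) % config.n_modules
        parent, parent_genes = chain_tail[m]
        subset = parent_genes[: max(1, len(parent_genes) // 2)]
        parents[term] = [parent]
        annotations[term] = list(subset)
        names[term] = f"module {m} subprocess (depth below {parent})"
        chain_tail[m] = (term, subset)
    return parents, annotations, module_terms, names


def simulate_expression(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic dataset.

    Returns
    -------
    matrix
        genes x samples expression DataFrame (non-negative, NaN = missing).
    annotation
        per-sample table with columns ``sample_id``, ``tissue_type``, ``state``.
    truth
        the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    tissues = _tissue_names(config.n_tissues)
    n_samples = config.n_tissues * config.samples_per_tissue

    sample_ids = [
        f"{t}_s{k:02d}" for t in tissues for k in range(config.samples_per_tissue)
    ]
    tissue_of_sample = np.repeat(np.arange(config.n_tissues), config.samples_per_tissue)

    mu = rng.uniform(*config.background_mean_range, size=config.n_genes)
    sd = rng.uniform(*config.background_sd_range, size=config.n_genes)

    if config.active_tissues_per_gene is not None:
        active = np.zeros((config.n_genes, config.n_tissues), dtype=np.int8)
        for g in range(config.n_genes):
            chosen = rng.choice(
                config.n_tissues, size=config.active_tissues_per_gene, replace=False
            )
            active[g, chosen] = 1
    else:
        active = (
            rng.random((config.n_genes, config.n_tissues))
            < config.active_tissue_fraction
        ).astype(np.int8)

    noise = rng.standard_normal((config.n_genes, n_samples))
    factors = rng.standard_normal((config.n_modules, n_samples))
    missing = (
        rng.random((config.n_genes, n_samples)) < config.missing_rate
        if config.missing_rate > 0
        else None
    )

    shift = config.active_shift_sd * sd[:, None] * active[:, tissue_of_sample]
    values = mu[:, None] + shift + sd[:, None] * noise

    membership = _module_of(config)
    if config.module_factor_sd > 0:
        for gi, g in enumerate(genes):
            m = membership.get(g)
            if m is not None:
                values[gi] += config.module_factor_sd * sd[gi] * factors[m]

    np.clip(values, 0.0, None, out=values)
    if missing is not None:
        values[missing] = np.nan

    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    matrix.index.name = "gene"
    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue_type": [tissues[t] for t in tissue_of_sample],
            "state": [tissues[t].split("_")[0] for t in tissue_of_sample],
        }
    )

    _, raw_annotations, module_terms, _ = _term_scheme(config)
    ontology = simulate_ontology(config)
    truth = SyntheticTruth(
        true_activity=pd.DataFrame(active, index=genes, columns=tissues),
        module_membership=membership,
        term_annotations={t: ontology.genes(t) for t in raw_annotations},
        marker_genes={m: genes[m * config.module_size] for m in range(config.n_modules)},
        module_terms=module_terms,
    )
    return matrix, annotation, truth


def simulate_ontology(config: SimulationConfig) -> Ontology:
    """Build the toy rooted term DAG matching :func:`simulate_expression`.

    One designated term per module annotates exactly that module's genes;
    remaining terms form chains below the module terms, each annotating the
    first half of its parent's genes. Annotations are closed under ancestor
    propagation, so the root annotates every annotated gene. The gene
    universe is the full simulated gene set.
    """
    parents, annotations, _, names = _term_scheme(config)
    return Ontology(
        parents, annotations, universe=_gene_ids(config.n_genes), names=names
    )
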