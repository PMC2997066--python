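"""Reusable study designs: simulation experiments the analysis scripts run.

Each function wires the synthetic generator to one downstream stage and
measures a recovery or calibration quantity against the planted truth.
They are thin, deterministic (seed-in, numbers-out) and shared between the
analysis drivers and the test suite.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .activity import background_cutoff, call_activity, compute_thresholds, entropy_profile
from .config import SimulationConfig, WalkConfig
from .coexpression import neighborhood_set, pairwise_correlation, random_walk_profile
from .enrichment import enrich_set
from .pipeline import _paired_tissues
from .simulate import simulate_expression, simulate_ontology
from .taxonomy import gain_loss

__all__ = [
    "RECOVERY_CONFIG",
    "COEXPRESSION_CONFIG",
    "background_false_activation",
    "activity_recovery",
    "gain_loss_mismatches",
    "module_term_association",
]

#: Study conditions for planted-activity recovery: 30 tissues of 20 replicate
#: samples, an 8-background-SD active shift and 5% missing values.
RECOVERY_CONFIG = SimulationConfig(
    n_genes=40,
    n_tissues=30,
    samples_per_tissue=20,
    active_shift_sd=8.0,
    missing_rate=0.05,
    n_modules=2,
    module_size=5,
    n_terms=7,
)

#: Study conditions for the co-expression/enrichment stages: the corpus-scale
#: tissue count (99 tissue classes) keeps activity-coincidence correlations
#: between unrelated genes small relative to the strong module factor, and
#: 1500 genes give the nearest-rank top-99.9% gate two valid links per gene
#: so walks branch.
COEXPRESSION_CONFIG = SimulationConfig(
    n_genes=1500,
    n_tissues=99,
    samples_per_tissue=6,
    active_shift_sd=8.0,
    missing_rate=0.05,
    n_modules=5,
    module_size=20,
    module_factor_sd=3.0,
    n_terms=16,
)


def background_false_activation(
    seed: int,
    n_genes: int = 200,
    n_tissues: int = 30,
    samples_per_tissue: int = 20,
    n_active_tissues: int = 5,
    active_shift_sd: float = 8.0,
    window_frac: float = 0.05,
    step_frac: float = 0.01,
) -> Dict[str, float]:
    """Per-sample false-activation rate of the entropy-window cutoff.

    Simulates genes with a shared Gaussian background across all tissues and
    an active component shifted ``active_shift_sd`` background SDs upwards in
    exactly ``n_active_tissues`` tissues, computes each gene's cutoff from
    the full sample set, and reports the mean over genes of the fraction of
    background-tissue samples strictly above the cutoff.
    """
    cfg = SimulationConfig(
        n_genes=n_genes,
        n_tissues=n_tissues,
        samples_per_tissue=samples_per_tissue,
        active_shift_sd=active_shift_sd,
        active_tissues_per_gene=n_active_tissues,
        n_modules=1,
        module_size=1,
        module_factor_sd=0.0,
        missing_rate=0.0,
        n_terms=2,
        seed=seed,
    )
    matrix, annotation, truth = simulate_expression(cfg)
    labels = annotation.set_index("sample_id").loc[matrix.columns, "tissue_type"]
    tissue_of_sample = labels.to_numpy()
    exceed = []
    for gene, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        prof = entropy_profile(vals, tissue_of_sample, window_frac, step_frac)
        thr = background_cutoff(prof, vals, gene)
        active_tissues = set(
            truth.true_activity.columns[truth.true_activity.loc[gene] == 1]
        )
        bg = vals[~np.isin(tissue_of_sample, list(active_tissues))]
        exceed.append(float((bg > thr.cutoff).mean()))
    exceed = np.asarray(exceed)
    return {
        "mean_exceedance": float(exceed.mean()),
        "sem": float(exceed.std(ddof=1) / np.sqrt(len(exceed))),
        "n_genes": n_genes,
    }


def _recovery_rates(
    activity: pd.DataFrame, truth_activity: pd.DataFrame
) -> Tuple[float, float]:
    act = activity[truth_activity.columns].to_numpy()
    tru = truth_activity.to_numpy()
    tp = int(((act == 1) & (tru == 1)).sum())
    fn = int(((act == 0) & (tru == 1)).sum())
    tn = int(((act == 0) & (tru == 0)).sum())
    fp = int(((act == 1) & (tru == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def activity_recovery(
    seeds: range,
    config: SimulationConfig = RECOVERY_CONFIG,
    active_shift_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of activity calls vs planted truth per seed."""
    rows = []
    for seed in seeds:
        overrides = {"seed": int(seed)}
        if active_shift_sd is not None:
            overrides["active_shift_sd"] = active_shift_sd
        cfg = dataclasses.replace(config, **overrides)
        matrix, annotation, truth = simulate_expression(cfg)
        thresholds = compute_thresholds(matrix, annotation)
        activity = call_activity(matrix, annotation, thresholds)
        sens, spec = _recovery_rates(activity, truth.true_activity)
        rows.append({"seed": int(seed), "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def gain_loss_mismatches(
    seed: int, config: SimulationConfig = RECOVERY_CONFIG
) -> Dict[str, object]:
    """Genes whose called gain/loss status differs from the planted one,
    across every paired healthy/malignant tissue of one simulated dataset."""
    cfg = dataclasses.replace(config, seed=seed)
    matrix, annotation, truth = simulate_expression(cfg)
    activity = call_activity(matrix, annotation, compute_thresholds(matrix, annotation))
    mismatched = set()
    pairs = _paired_tissues(activity.columns)
    for ref, cmp_ in pairs:
        called = gain_loss(activity, ref, cmp_)
        planted = gain_loss(truth.true_activity, ref, cmp_)
        mismatched |= called.gained ^ planted.gained
        mismatched |= called.lost ^ planted.lost
    return {"n_pairs": len(pairs), "mismatched_genes": sorted(mismatched)}


def module_term_association(
    seed: int,
    config: SimulationConfig = COEXPRESSION_CONFIG,
    n_walks: int = 500,
    walk_length: int = 5,
    percentile: float = 0.999,
    min_overlap: int = 30,
    min_visits: int = 2,
    alpha: float = 0.01,
) -> Dict[str, float]:
    """End-to-end module recovery through walks and enrichment.

    For every module gene: walk its co-expression neighborhood, test for
    term over-representation, and record whether its own module's term is
    accepted and how many off-module leaf terms are.  Returns the fraction
    of module genes associated with their own term and the median number of
    accepted off-module leaf terms.
    """
    cfg = dataclasses.replace(config, seed=seed)
    matrix, _, truth = simulate_expression(cfg)
    ontology = simulate_ontology(cfg)
    graph = pairwise_correlation(matrix, min_overlap=min_overlap, percentile=percentile)
    universe = list(matrix.index)
    leaves = ontology.leaves()

    associated = 0
    off_module_counts: List[int] = []
    walk_ss = np.random.SeedSequence([int(seed), 0xA15])
    for i, gene in enumerate(sorted(truth.module_membership)):
        rng_seed = int(
            np.random.SeedSequence([int(walk_ss.generate_state(1)[0] % 2**31), i])
            .generate_state(1)[0]
            % 2**31
        )
        profile = random_walk_profile(
            graph, gene, WalkConfig(n_walks, walk_length, rng_seed)
        )
        hood = neighborhood_set(profile, min_visits)
        table = enrich_set(hood, ontology, alpha=alpha, universe=universe)
        accepted = (
            set(table.loc[table["accepted"], "term"]) if len(table) else set()
        )
        own_term = truth.module_terms[truth.module_membership[gene]]
        associated += own_term in accepted
        own_genes = ontology.genes(own_term)
        off = [
            t
            for t in accepted
            if t in leaves and not (ontology.genes(t) <= own_genes)
        ]
        off_module_counts.append(len(off))
    n = len(truth.module_membership)
    return {
        "fraction_associated": associated / n,
        "median_off_module_leaf_terms": float(np.median(off_module_counts)),
        "n_module_genes": n,
    }
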