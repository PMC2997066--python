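"""End-to-end orchestration of the analysis stages with a reproducibility manifest.

Stages communicate through the plain-text artifacts declared per module
(TSV / GMT / OBO / Newick), so running :func:`run_pipeline` is equivalent to
chaining the individual CLI subcommands on the same output directory with
the same master seed.  One global seed deterministically derives per-stage
seeds, and a JSON manifest records the effective configuration, seeds,
per-stage row counts and SHA-256 checksums of every artifact.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .activity import call_activity, compute_thresholds
from .config import ActivityParams, SimulationConfig, WalkConfig
from .coexpression import (
    CorrelationGraph,
    neighborhood_set,
    pairwise_correlation,
    random_walk_profile,
)
from .enrichment import enrich_set, filter_terms, kinase_term_matrix, semantic_ordering
from .ontology import Ontology
from .simulate import simulate_expression, simulate_ontology
from .taxonomy import (
    changed_fraction,
    cluster_binary,
    cut_groups,
    gain_loss,
    group_activity_share,
    group_purity,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run.

    Defaults equal the source analysis' stated values: 5% entropy window,
    2x-SD cutoff, top-99.9-percentile link gate, 500 walks of 5 steps,
    alpha = 0.01 and a >= 15-seed term filter.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    simulation: Optional[SimulationConfig] = field(default_factory=SimulationConfig)
    expression_path: Optional[str] = None
    annotation_path: Optional[str] = None
    obo_path: Optional[str] = None
    gmt_path: Optional[str] = None
    activity: ActivityParams = field(default_factory=ActivityParams)
    n_walks: int = 500
    walk_length: int = 5
    percentile: float = 0.999
    min_overlap: int = 30
    min_visits: int = 2
    alpha: float = 0.01
    min_seeds: int = 15
    bh_correction: bool = False
    tissue_linkage: str = "complete"
    gene_linkage: str = "complete"
    k_tissue_groups: int = 4
    k_gene_groups: int = 6
    seed_genes: Optional[List[str]] = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if data.get("simulation") is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        if data.get("activity") is not None:
            data["activity"] = ActivityParams(**data["activity"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ----------------------------------------------------------------------
# stages — each reads its inputs from, and writes its outputs to, outdir


def stage_simulate(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if sim is None:
        raise ValueError("stage_simulate requires a simulation config")
    sim = dataclasses.replace(sim, seed=stage_seed(config.seed, "simulate"))
    matrix, annotation, truth = simulate_expression(sim)
    ontology = simulate_ontology(sim)
    kio.write_expression(out / "expression.tsv", matrix)
    kio.write_annotation(out / "annotation.tsv", annotation)
    kio.write_obo(out / "ontology.obo", ontology)
    kio.write_gmt(
        out / "annotations.gmt",
        {t: ontology.genes(t) for t in ontology.terms if ontology.genes(t)},
        descriptions=ontology.names,
    )
    kio.write_activity(out / "truth_activity.tsv", truth.true_activity)
    pd.Series(truth.module_membership, name="module").rename_axis("gene").to_csv(
        out / "truth_modules.tsv", sep="\t"
    )
    return {"genes": matrix.shape[0], "samples": matrix.shape[1]}


def _load_inputs(config: PipelineConfig):
    out = Path(config.outdir)
    expr = config.expression_path or out / "expression.tsv"
    ann = config.annotation_path or out / "annotation.tsv"
    matrix = kio.read_expression(expr)
    annotation = kio.read_annotation(ann)
    extra = set(matrix.columns) - set(annotation["sample_id"])
    missing = set(annotation["sample_id"]) - set(matrix.columns)
    if extra or missing:
        raise ValueError(
            "sample ids are inconsistent between expression and annotation; "
            f"unannotated: {sorted(extra)[:5]}, absent from matrix: "
            f"{sorted(missing)[:5]}"
        )
    return matrix, annotation


def _load_ontology(config: PipelineConfig, universe) -> Ontology:
    out = Path(config.outdir)
    obo = config.obo_path or out / "ontology.obo"
    gmt = config.gmt_path or out / "annotations.gmt"
    return kio.ontology_from_obo(obo, gmt, universe=universe)


def stage_activity(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    matrix, annotation = _load_inputs(config)
    thresholds = compute_thresholds(matrix, annotation, config.activity)
    activity = call_activity(matrix, annotation, thresholds)
    kio.write_thresholds(out / "thresholds.tsv", thresholds)
    kio.write_activity(out / "activity.tsv", activity)
    return {"thresholds": len(thresholds), "active_calls": int(activity.to_numpy().sum())}


def stage_cluster(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    activity = kio.read_activity(out / "activity.tsv")
    annotation = kio.read_annotation(
        config.annotation_path or out / "annotation.tsv"
    )
    tissue_tree = cluster_binary(activity, "tissues", config.tissue_linkage)
    gene_tree = cluster_binary(activity, "genes", config.gene_linkage)
    kio.write_newick(out / "tissue_tree.nwk", tissue_tree.linkage, tissue_tree.items)
    kio.write_newick(out / "gene_tree.nwk", gene_tree.linkage, gene_tree.items)

    tissue_groups = cut_groups(tissue_tree, config.k_tissue_groups)
    gene_groups = cut_groups(gene_tree, config.k_gene_groups)
    state_of = dict(
        annotation.drop_duplicates("tissue_type")[["tissue_type", "state"]].values
    )
    purity = group_purity(tissue_groups, state_of)
    purity.to_csv(out / "tissue_group_purity.tsv", sep="\t")
    pd.Series(tissue_groups, name="group").rename_axis("tissue").to_csv(
        out / "tissue_groups.tsv", sep="\t"
    )
    pd.Series(gene_groups, name="group").rename_axis("gene").to_csv(
        out / "gene_groups.tsv", sep="\t"
    )

    shares = []
    for gg in sorted(set(gene_groups.values())):
        genes = [g for g, grp in gene_groups.items() if grp == gg]
        for tg in sorted(set(tissue_groups.values())):
            tissues = [t for t, grp in tissue_groups.items() if grp == tg]
            shares.append(
                {
                    "gene_group": gg,
                    "tissue_group": tg,
                    "activity_share_pct": group_activity_share(activity, genes, tissues),
                }
            )
    pd.DataFrame(shares).to_csv(out / "group_activity_share.tsv", sep="\t", index=False)
    return {"tissue_groups": config.k_tissue_groups, "gene_groups": config.k_gene_groups}


def _paired_tissues(tissues) -> List[tuple]:
    """(healthy_X, malignant_X) pairs matched by label suffix."""
    healthy = {t.split("_", 1)[1]: t for t in tissues if t.startswith("healthy_")}
    malignant = {t.split("_", 1)[1]: t for t in tissues if t.startswith("malignant_")}
    return [(healthy[s], malignant[s]) for s in sorted(healthy) if s in malignant]


def stage_gainloss(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    activity = kio.read_activity(out / "activity.tsv")
    pairs = _paired_tissues(activity.columns)
    summary, detail = [], []
    for ref, cmp_ in pairs:
        report = gain_loss(activity, ref, cmp_)
        summary.append(
            {
                "reference": ref,
                "comparison": cmp_,
                "n_gained": len(report.gained),
                "n_lost": len(report.lost),
                "changed_pct": changed_fraction(report),
            }
        )
        for g in sorted(report.gained):
            detail.append({"reference": ref, "comparison": cmp_, "gene": g, "change": "gained"})
        for g in sorted(report.lost):
            detail.append({"reference": ref, "comparison": cmp_, "gene": g, "change": "lost"})
    pd.DataFrame(summary).to_csv(out / "gainloss_summary.tsv", sep="\t", index=False)
    pd.DataFrame(detail, columns=["reference", "comparison", "gene", "change"]).to_csv(
        out / "gainloss_genes.tsv", sep="\t", index=False
    )
    return {"tissue_pairs": len(pairs), "changed_genes": len(detail)}


def stage_coexpress(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    matrix, _ = _load_inputs(config)
    graph = pairwise_correlation(matrix, config.min_overlap, config.percentile)
    edges = []
    for u, targets in graph.valid.items():
        for v in targets:
            edges.append({"source": u, "target": v, "r": graph.corr.loc[u, v]})
    pd.DataFrame(edges, columns=["source", "target", "r"]).to_csv(
        out / "valid_links.tsv", sep="\t", index=False
    )
    return {"genes": len(graph.genes), "valid_links": len(edges)}


def _graph_from_artifacts(config: PipelineConfig) -> CorrelationGraph:
    """Rebuild the gated graph from the persisted valid-link edge list.

    Only the link structure is needed for walking; the correlation table is
    reconstructed sparsely (NaN elsewhere)."""
    out = Path(config.outdir)
    matrix, _ = _load_inputs(config)
    genes = list(matrix.index)
    edges = pd.read_csv(out / "valid_links.tsv", sep="\t")
    corr = pd.DataFrame(np.nan, index=genes, columns=genes)
    valid: Dict[str, tuple] = {g: () for g in genes}
    for u, sub in edges.groupby("source"):
        valid[u] = tuple(sorted(sub["target"]))
        corr.loc[u, list(sub["target"])] = sub.set_index("target")["r"].reindex(
            sorted(sub["target"])
        ).to_numpy()
    return CorrelationGraph(corr, valid, config.percentile, config.min_overlap)


def stage_walk(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    graph = _graph_from_artifacts(config)
    seeds = config.seed_genes or graph.genes
    base = stage_seed(config.seed, "walk")
    prof_rows, hood_rows = [], []
    for i, seed_gene in enumerate(seeds):
        rng_seed = int(
            np.random.SeedSequence([base, i]).generate_state(1)[0] % (2**31)
        )
        wc = WalkConfig(config.n_walks, config.walk_length, rng_seed)
        profile = random_walk_profile(graph, seed_gene, wc)
        for gene, visits in sorted(profile.counts.items()):
            prof_rows.append(
                {
                    "seed": seed_gene,
                    "gene": gene,
                    "visits": visits,
                    "n_walks": profile.n_walks,
                    "terminated_early": profile.terminated_early,
                }
            )
        for gene in sorted(neighborhood_set(profile, config.min_visits)):
            hood_rows.append({"seed": seed_gene, "gene": gene})
    pd.DataFrame(
        prof_rows, columns=["seed", "gene", "visits", "n_walks", "terminated_early"]
    ).to_csv(out / "visit_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(hood_rows, columns=["seed", "gene"]).to_csv(
        out / "neighborhoods.tsv", sep="\t", index=False
    )
    return {"seeds_walked": len(seeds), "neighborhood_genes": len(hood_rows)}


def stage_enrich(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.outdir)
    matrix, _ = _load_inputs(config)
    universe = list(matrix.index)
    ontology = _load_ontology(config, universe)
    hoods = pd.read_csv(out / "neighborhoods.tsv", sep="\t")
    seeds = config.seed_genes or universe
    tables = {}
    for seed_gene in seeds:
        genes = hoods.loc[hoods["seed"] == seed_gene, "gene"]
        tables[seed_gene] = enrich_set(
            genes,
            ontology,
            alpha=config.alpha,
            universe=universe,
            bh_correction=config.bh_correction,
        )
    combined = pd.concat(
        [t.assign(seed=s) for s, t in tables.items() if len(t)],
        ignore_index=True,
    ) if any(len(t) for t in tables.values()) else pd.DataFrame()
    combined.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    term_matrix = kinase_term_matrix(tables)
    term_matrix.to_csv(out / "seed_term_matrix.tsv", sep="\t")
    filtered = filter_terms(term_matrix, config.min_seeds)
    filtered.to_csv(out / "seed_term_matrix_filtered.tsv", sep="\t")
    n_ordered = 0
    if filtered.shape[1] >= 2:
        ordering = semantic_ordering(list(filtered.columns), ontology)
        kio.write_newick(out / "term_ordering.nwk", ordering.linkage, ordering.ordered_terms)
        Path(out / "term_order.txt").write_text("\n".join(ordering.ordered_terms) + "\n")
        n_ordered = len(ordering.ordered_terms)
    return {
        "seeds_enriched": len(tables),
        "accepted_terms": int(term_matrix.to_numpy().sum()),
        "terms_retained": int(filtered.shape[1]),
        "terms_ordered": n_ordered,
    }


STAGES = [
    ("simulate", stage_simulate),
    ("activity", stage_activity),
    ("cluster", stage_cluster),
    ("gainloss", stage_gainloss),
    ("coexpress", stage_coexpress),
    ("walk", stage_walk),
    ("enrich", stage_enrich),
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and write a manifest; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    counts: Dict[str, dict] = {}
    for name, fn in STAGES:
        if name == "simulate" and config.simulation is None:
            continue
        log.info("stage %s", name)
        try:
            counts[name] = fn(config)
        except Exception:
            log.error("stage %s failed", name)
            raise
    import importlib.metadata as _md

    artifacts = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": counts,
        "artifacts": artifacts,
        "versions": {
            "kinact": _md.version("kinact"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
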