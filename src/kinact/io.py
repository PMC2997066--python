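"""Readers and writers for the plain-text artifacts of the pipeline.

Expression: TSV with gene ids in the first column, sample ids in the header
row, empty cell or ``NA`` for missing.  Annotation: TSV with columns
``sample_id, tissue_type, state``.  Gene sets: GMT.  Ontology: minimal OBO
subset (``[Term]``, ``id``, ``name``, ``is_a``) read through :mod:`obonet`.
Dendrograms: Newick with merge heights as branch lengths.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import obonet
import pandas as pd
import skbio

from .errors import ParseError
from .ontology import Ontology

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_activity",
    "write_activity",
    "read_thresholds",
    "write_thresholds",
    "read_gmt",
    "write_gmt",
    "read_obo",
    "write_obo",
    "ontology_from_obo",
    "write_newick",
]

VALID_STATES = {"healthy", "malignant"}


def read_expression(path) -> pd.DataFrame:
    """Gene x sample expression TSV; ``NA`` or empty cell means missing."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(path, f"cannot parse expression table: {exc}") from exc
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        bad = non_numeric[0]
        row = df[bad].map(lambda v: isinstance(v, str)).idxmax()
        raise ParseError(
            path,
            f"non-numeric value {df.loc[row, bad]!r} for gene {row!r}",
            column=list(df.columns).index(bad) + 2,
        )
    df.index.name = "gene"
    df.index = df.index.astype(str)
    return df


def write_expression(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path) -> pd.DataFrame:
    """Sample annotation TSV with columns sample_id, tissue_type, state."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(path, f"cannot parse annotation table: {exc}") from exc
    required = ["sample_id", "tissue_type", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, f"missing columns {missing}", line=1)
    bad = df.index[~df["state"].isin(VALID_STATES)]
    if len(bad):
        raise ParseError(
            path,
            f"state must be one of {sorted(VALID_STATES)}, got "
            f"{df.loc[bad[0], 'state']!r}",
            line=int(bad[0]) + 2,
        )
    return df[required]


def write_annotation(path, annotation: pd.DataFrame) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_activity(path) -> pd.DataFrame:
    """Binary gene x tissue activity TSV."""
    df = read_expression(path)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ParseError(path, "activity matrix entries must be 0 or 1")
    out = df.astype(np.int8)
    out.columns.name = "tissue"
    return out


def write_activity(path, activity: pd.DataFrame) -> None:
    activity.to_csv(path, sep="\t")


def read_thresholds(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(path, f"cannot parse thresholds table: {exc}") from exc
    required = ["midpoint", "sd_below", "cutoff", "degenerate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, f"missing columns {missing}", line=1)
    df["degenerate"] = df["degenerate"].fillna("")
    return df


def write_thresholds(path, thresholds: pd.DataFrame) -> None:
    thresholds.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path) -> Dict[str, Set[str]]:
    """GMT gene sets: tab-separated ``name, description, gene, gene, ...``."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    path, "GMT line needs name, description and >= 1 gene", line=lineno
                )
            out[fields[0]] = set(g for g in fields[2:] if g)
    return out


def write_gmt(path, gene_sets: Mapping[str, Iterable[str]], descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in gene_sets:
            genes = sorted(gene_sets[name])
            fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def read_obo(path):
    """Minimal OBO term DAG as (parents, names) mappings (is_a links only)."""
    try:
        graph = obonet.read_obo(path)
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise ParseError(path, f"cannot parse OBO file: {exc}") from exc
    parents: Dict[str, List[str]] = {}
    names: Dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        parents[term] = sorted(data.get("is_a", []))
        if "name" in data:
            names[term] = data["name"]
    # obonet stores is_a as edges, not node attributes; collect from edges too
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, [])
            if parent not in parents[child]:
                parents[child].append(parent)
    return parents, names


def write_obo(path, ontology: Ontology) -> None:
    """Minimal OBO subset: [Term] stanzas with id, name and is_a lines."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(ontology.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            name = ontology.names.get(term)
            if name:
                fh.write(f"name: {name}\n")
            for parent in sorted(ontology.parents(term)):
                fh.write(f"is_a: {parent}\n")


def ontology_from_obo(
    obo_path, gmt_path=None, universe: Optional[Iterable[str]] = None
) -> Ontology:
    """Ontology from a minimal OBO DAG plus (optionally) GMT annotations."""
    parents, names = read_obo(obo_path)
    annotations = read_gmt(gmt_path) if gmt_path is not None else {}
    unknown = [t for t in annotations if t not in parents]
    if unknown:
        raise ParseError(
            gmt_path, f"GMT terms absent from the OBO DAG, e.g. {unknown[:3]}"
        )
    return Ontology(parents, annotations, universe=universe, names=names)


def write_newick(path, linkage: np.ndarray, leaf_names: Sequence[str]) -> None:
    """Dendrogram as Newick with merge heights as branch lengths."""
    tree = skbio.TreeNode.from_linkage_matrix(linkage, list(leaf_names))
    tree.write(str(path), format="newick")
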