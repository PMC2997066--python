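"""A rooted is_a term DAG with gene annotations closed under ancestor propagation.

This is a minimal stand-in for the biological-process branch of the Gene
Ontology: terms form a directed acyclic graph with a single root, each term
carries a set of annotated genes, and annotating a gene to a term implicitly
annotates it to every ancestor of that term (the "true-path rule").
"""
from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set

import networkx as nx

from .errors import ConfigError


class Ontology:
    """Term DAG plus propagated gene annotations.

    Parameters
    ----------
    parents
        Mapping term -> iterable of parent term ids (``is_a`` links).
        Terms that appear only as parents are created implicitly.
    annotations
        Mapping term -> iterable of directly annotated gene ids.
    universe
        The gene universe used as the enrichment background. Defaults to
        the union of all annotated genes.
    names
        Optional human-readable term names.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        annotations: Mapping[str, Iterable[str]],
        universe: Optional[Iterable[str]] = None,
        names: Optional[Mapping[str, str]] = None,
    ) -> None:
        graph = nx.DiGraph()  # edges run child -> parent
        for term, ps in parents.items():
            graph.add_node(term)
            for p in ps:
                graph.add_edge(term, p)
        for term in annotations:
            graph.add_node(term)
        if graph.number_of_nodes() == 0:
            raise ConfigError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(graph):
            raise ConfigError("ontology is_a graph contains a cycle")
        roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ConfigError(f"ontology must have exactly one root, found {sorted(roots)}")
        self.graph = graph
        self.root: str = roots[0]
        self.names: Dict[str, str] = dict(names or {})

        # Propagate annotations to ancestors (true-path closure).
        closed: Dict[str, Set[str]] = {t: set(annotations.get(t, ())) for t in graph.nodes}
        for term in nx.topological_sort(graph):  # children before parents
            for parent in graph.successors(term):
                closed[parent] |= closed[term]
        self.annotations: Dict[str, FrozenSet[str]] = {
            t: frozenset(g) for t, g in closed.items()
        }

        annotated = frozenset().union(*self.annotations.values())
        self.universe: FrozenSet[str] = (
            frozenset(universe) if universe is not None else annotated
        )
        stray = annotated - self.universe
        if stray:
            raise ConfigError(
                f"{len(stray)} annotated genes are outside the universe, e.g. "
                f"{sorted(stray)[:3]}"
            )

    # ------------------------------------------------------------------
    @property
    def terms(self):
        return list(self.graph.nodes)

    def genes(self, term: str) -> FrozenSet[str]:
        """Propagated annotation set of ``term``."""
        return self.annotations[term]

    def parents(self, term: str) -> Set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> Set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str, include_self: bool = True) -> Set[str]:
        anc = nx.descendants(self.graph, term)  # child->parent edges
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = False) -> Set[str]:
        dec = nx.ancestors(self.graph, term)
        if include_self:
            dec.add(term)
        return dec

    def leaves(self) -> Set[str]:
        return {t for t in self.graph.nodes if self.graph.in_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:
        return (
            f"Ontology({len(self)} terms, root={self.root!r}, "
            f"universe={len(self.universe)} genes)"
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_gene_sets(
        cls,
        gene_sets: Mapping[str, Iterable[str]],
        universe: Optional[Iterable[str]] = None,
        root: str = "ROOT",
    ) -> "Ontology":
        """Build a flat ontology (every term a child of a synthetic root)
        from plain gene sets, e.g. parsed from a GMT file."""
        parents = {t: [root] for t in gene_sets if t != root}
        parents[root] = []
        return cls(parents, dict(gene_sets), universe=universe)
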