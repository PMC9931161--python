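"""The heterogeneous gene-disease graph.

Two typed node sets (genes, diseases) and two typed undirected edge sets:
gene-disease association edges and tissue-derived gene-gene edges. The
gene-gene layer is built as one clique per tissue (genes reported in the
same tissue are pairwise connected), and on integration a gene-gene edge
survives only if at least one endpoint is a gene of the gene-disease
layer — gene pairs with no disease context contribute nothing to link
prediction and would only dilute the walks.

Edge removal (to form the train-time graph G') never deletes nodes:
every labeled pair must keep an embedding even if a disease loses all
of its edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .tables_io import AssociationRecord

GdEdge = tuple[str, str]  # (gene, disease)
GgEdge = tuple[str, str]  # (gene, gene), lexicographically ordered


class GraphError(ValueError):
    """Structural violation while building or editing the graph."""


def gg_key(a: str, b: str) -> GgEdge:
    """Canonical unordered key for a gene-gene edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class HetGraph:
    disease_nodes: set[str] = field(default_factory=set)
    gene_nodes: set[str] = field(default_factory=set)
    gd_edges: set[GdEdge] = field(default_factory=set)
    gg_edges: set[GgEdge] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.disease_nodes & self.gene_nodes
        if overlap:
            raise GraphError(f"labels used as both gene and disease: {sorted(overlap)[:5]}")
        for g, d in self.gd_edges:
            if g not in self.gene_nodes or d not in self.disease_nodes:
                raise GraphError(f"gd edge ({g}, {d}) has an unknown endpoint")
        for a, b in self.gg_edges:
            if a == b:
                raise GraphError(f"self-loop on {a}")
            if a not in self.gene_nodes or b not in self.gene_nodes:
                raise GraphError(f"gg edge ({a}, {b}) has an unknown endpoint")
            if (a, b) != gg_key(a, b):
                raise GraphError(f"gg edge ({a}, {b}) not canonically ordered")
        self._adj: dict[str, set[str]] | None = None

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return self.disease_nodes | self.gene_nodes

    def n_edges(self) -> int:
        return len(self.gd_edges) + len(self.gg_edges)

    def is_disease(self, node: str) -> bool:
        return node in self.disease_nodes

    def has_gd_edge(self, gene: str, disease: str) -> bool:
        return (gene, disease) in self.gd_edges

    def adjacent(self, a: str, b: str) -> bool:
        """True if any edge (either type) joins a and b."""
        return b in self.adjacency().get(a, ())

    def adjacency(self) -> dict[str, set[str]]:
        """Untyped neighbor sets over both edge types (cached)."""
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for g, d in self.gd_edges:
                adj[g].add(d)
                adj[d].add(g)
            for a, b in self.gg_edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = adj
        return self._adj

    def genes_of(self, disease: str) -> set[str]:
        """Genes with an association edge to ``disease``."""
        if disease not in self.disease_nodes:
            raise GraphError(f"unknown disease {disease!r}")
        return {g for g, d in self.gd_edges if d == disease}

    def gd_degree(self, disease: str) -> int:
        return len(self.genes_of(disease))

    def copy(self) -> "HetGraph":
        return HetGraph(
            disease_nodes=set(self.disease_nodes),
            gene_nodes=set(self.gene_nodes),
            gd_edges=set(self.gd_edges),
            gg_edges=set(self.gg_edges),
        )


def build_gd_graph(associations: Iterable[AssociationRecord]) -> HetGraph:
    """One association edge per distinct (gene, disease) pair."""
    associations = list(associations)
    if not associations:
        raise GraphError("no association records")
    genes = {r.gene_symbol for r in associations}
    diseases = {r.disease_id for r in associations}
    edges = {(r.gene_symbol, r.disease_id) for r in associations}
    return HetGraph(disease_nodes=diseases, gene_nodes=genes, gd_edges=edges)


def build_gg_graph(gene_tissue_pairs: Iterable[tuple[str, str]]) -> HetGraph:
    """Connect genes that share at least one tissue (a clique per tissue)."""
    by_tissue: dict[str, set[str]] = {}
    genes: set[str] = set()
    for gene, tissue in gene_tissue_pairs:
        by_tissue.setdefault(tissue, set()).add(gene)
        genes.add(gene)
    edges: set[GgEdge] = set()
    for members in by_tissue.values():
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                edges.add((a, b))
    return HetGraph(gene_nodes=genes, gg_edges=edges)


def integrate(gd: HetGraph, gg: HetGraph) -> HetGraph:
    """Union of both layers under the exclusion rule.

    A gene-gene edge is kept iff at least one endpoint is a gene of the
    gene-disease layer; genes appearing only in discarded edges are not
    added to the integrated graph.
    """
    if gd.gg_edges:
        raise GraphError("first argument must contain only gene-disease edges")
    if gg.gd_edges:
        raise GraphError("second argument must contain only gene-gene edges")
    kept = {(a, b) for a, b in gg.gg_edges if a in gd.gene_nodes or b in gd.gene_nodes}
    genes = set(gd.gene_nodes)
    for a, b in kept:
        genes.add(a)
        genes.add(b)
    return HetGraph(
        disease_nodes=set(gd.disease_nodes),
        gene_nodes=genes,
        gd_edges=set(gd.gd_edges),
        gg_edges=kept,
    )


def remove_edges(g: HetGraph, edges: Iterable[GdEdge]) -> HetGraph:
    """Return a copy with the given gene-disease edges deleted.

    Nodes are retained even if isolated, so downstream embedding covers
    every endpoint of a held-out pair.
    """
    edges = set(edges)
    missing = edges - g.gd_edges
    if missing:
        raise GraphError(f"edges not in graph: {sorted(missing)[:5]}")
    out = g.copy()
    out.gd_edges -= edges
    out._adj = None
    return out


# -- serialization -------------------------------------------------------


def save_graph(g: HetGraph, path: str | Path) -> None:
    """Write as a typed edge-list TSV; isolated nodes get node rows."""
    touched: set[str] = set()
    for a, b in g.gd_edges | g.gg_edges:
        touched.add(a)
        touched.add(b)
    with open(path, "w") as fh:
        fh.write("record_type\tnode_a\tnode_b\n")
        for d in sorted(g.disease_nodes):
            fh.write(f"disease\t{d}\t\n")
        for gene in sorted(g.gene_nodes):
            fh.write(f"gene\t{gene}\t\n")
        for gene, d in sorted(g.gd_edges):
            fh.write(f"gd\t{gene}\t{d}\n")
        for a, b in sorted(g.gg_edges):
            fh.write(f"gg\t{a}\t{b}\n")


def load_graph(path: str | Path) -> HetGraph:
    diseases: set[str] = set()
    genes: set[str] = set()
    gd: set[GdEdge] = set()
    gg: set[GgEdge] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["record_type", "node_a", "node_b"]:
            raise GraphError(f"{path}: unrecognized graph file header")
        for line in fh:
            rec, a, b = line.rstrip("\n").split("\t")
            if rec == "disease":
                diseases.add(a)
            elif rec == "gene":
                genes.add(a)
            elif rec == "gd":
                gd.add((a, b))
            elif rec == "gg":
                gg.add(gg_key(a, b))
            else:
                raise GraphError(f"{path}: unknown record type {rec!r}")
    return HetGraph(disease_nodes=diseases, gene_nodes=genes, gd_edges=gd, gg_edges=gg)
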