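"""Undirected metabolic reaction graphs: metabolites as nodes, genes as edges.

Each reaction with substrate set S, product set P and catalyst genes G
contributes one edge (s, p) labelled G for every substrate s and product p
(bipartite substrate x product expansion; no substrate-substrate or
product-product edges, which would create co-substrate shortcuts).  Side
compounds (ubiquitous cofactors such as ATP or H2O) can be removed at build
time, which eliminates the shortcuts their over-representation creates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

from .kgml import COMPOUND, PathwayDocument

__all__ = [
    "MetabolicGraph",
    "build_graph",
    "graph_summary",
    "load_side_compounds",
    "default_side_compounds",
]


@dataclass
class MetabolicGraph:
    """An undirected multigraph of compounds linked by gene-labelled reactions.

    Parallel edges between the same compound pair coming from different
    reactions are preserved (they differ in ``reaction_id``).  ``gene_index``
    maps each gene KEGG ID to the set of compound nodes incident to any edge
    that gene labels — the node set a gene's SRD is measured from.
    """

    pathway_id: str
    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def genes(self) -> list[str]:
        return sorted(self.gene_index)

    def metabolites(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> Iterator[tuple[str, str, frozenset, str]]:
        """Yield (node_a, node_b, gene_ids, reaction_id) per parallel edge."""
        for a, b, data in self.graph.edges(data=True):
            yield a, b, data["genes"], data["reaction_id"]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "reaction_id": rid,
                "gene_ids": ";".join(sorted(genes)),
            }
            for a, b, genes, rid in self.edges()
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "reaction_id", "gene_ids"])

    def write_edgelist(self, path: str | Path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False)


def load_side_compounds(path: str | Path) -> frozenset[str]:
    """Read a side-compound list: one KEGG compound ID per line, '#' comments."""
    ids = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return frozenset(ids)


def default_side_compounds() -> frozenset[str]:
    """The packaged default cofactor list (ATP, H2O, NAD(P)H, CoA, Pi ...)."""
    text = resources.files("srdkit.data").joinpath("side_compounds.txt").read_text()
    ids = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return frozenset(ids)


def build_graph(
    doc: PathwayDocument,
    side_compounds: Iterable[str] = (),
) -> MetabolicGraph:
    """Convert a pathway document into a :class:`MetabolicGraph`.

    Compounds listed in ``side_compounds`` contribute neither nodes nor
    edges; a reaction whose non-side substrate or product set becomes empty
    contributes no edges.  Compounds that end up in no retained reaction are
    kept as isolated nodes (they can still be queried, giving infinite SRD).
    Reactions without catalysts contribute unlabelled (empty gene set) edges
    so metabolite-metabolite connectivity reflects the full network.

    Construction is deterministic: the same document and side list always
    produce an identical graph.
    """
    side = frozenset(side_compounds)
    g = MetabolicGraph(pathway_id=doc.pathway_id)

    for e in doc.entries:
        if e.kind == COMPOUND:
            for cid in e.kegg_ids:
                if cid not in side:
                    g.graph.add_node(cid)

    for r in doc.reactions:
        subs: list[str] = []
        for ref in r.substrates:
            subs.extend(c for c in doc.entry(ref).kegg_ids if c not in side)
        prods: list[str] = []
        for ref in r.products:
            prods.extend(c for c in doc.entry(ref).kegg_ids if c not in side)
        if not subs or not prods:
            continue
        genes: set[str] = set()
        for ref in r.catalysts:
            genes.update(doc.entry(ref).kegg_ids)
        gene_label = frozenset(genes)
        for s in dict.fromkeys(subs):
            for p in dict.fromkeys(prods):
                g.graph.add_edge(s, p, reaction_id=r.reaction_id, genes=gene_label)
                for gid in gene_label:
                    g.gene_index.setdefault(gid, set()).update((s, p))
    return g


def graph_summary(g: MetabolicGraph) -> dict:
    """Node/edge/gene/component counts plus the largest component's diameter.

    The diameter is the largest of all pairwise shortest-path lengths within
    the largest connected component (computed by BFS from every node).
    """
    if g.graph.number_of_nodes() == 0:
        raise ValueError("graph_summary: empty graph")
    simple = nx.Graph(g.graph)
    components = list(nx.connected_components(simple))
    largest = max(components, key=len)
    sub = simple.subgraph(largest)
    diameter = nx.diameter(sub) if len(largest) > 1 else 0
    return {
        "n_nodes": simple.number_of_nodes(),
        "n_edges": g.graph.number_of_edges(),
        "n_genes": len(g.gene_index),
        "n_components": len(components),
        "diameter_largest_component": diameter,
    }
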