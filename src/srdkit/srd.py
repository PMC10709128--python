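"""Shortest reactional distance (SRD) between genes and metabolites.

The SRD of a gene-metabolite pair is the minimum number of reaction steps
between any metabolite incident to one of the gene's catalyzed reactions and
the query metabolite, measured as unweighted shortest-path length on the
metabolic graph.  A metabolite that is itself a substrate or product of the
gene's reaction has SRD 0; each further reaction adds 1.

The outcome is three-valued:

* a non-negative integer when a path exists,
* ``Inf`` when gene and metabolite are both in the graph but disconnected,
* ``NA`` when the gene or the metabolite (or both) is absent from the graph,
  even if its KEGG ID is valid.  ``NA`` takes precedence over ``Inf``.

Distances are unit-weight, so breadth-first search and Dijkstra coincide; a
multi-source BFS from the gene's incident node set is the implementation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import MetabolicGraph

__all__ = [
    "SRDValue",
    "SRDResult",
    "node_distances",
    "srd",
    "srd_batch",
    "all_pairs_srd",
    "all_pairs_srd_matrix",
]

NUMERIC = "numeric"
INFINITE = "infinite"
NOT_AVAILABLE = "not_available"


@dataclass(frozen=True)
class SRDValue:
    """Three-valued SRD outcome: a number, ``Inf`` or ``NA``."""

    status: str
    value: int | None = None

    def __post_init__(self) -> None:
        if self.status == NUMERIC:
            if self.value is None or self.value < 0:
                raise ValueError("numeric SRD requires a non-negative value")
        elif self.status in (INFINITE, NOT_AVAILABLE):
            if self.value is not None:
                raise ValueError(f"{self.status} SRD carries no value")
        else:
            raise ValueError(f"unknown SRD status {self.status!r}")

    @classmethod
    def numeric(cls, value: int) -> "SRDValue":
        return cls(NUMERIC, int(value))

    @classmethod
    def infinite(cls) -> "SRDValue":
        return cls(INFINITE)

    @classmethod
    def not_available(cls) -> "SRDValue":
        return cls(NOT_AVAILABLE)

    @property
    def is_finite(self) -> bool:
        return self.status == NUMERIC

    def as_float(self) -> float:
        """Numeric value, ``inf`` for disconnected, ``nan`` for absent."""
        if self.status == NUMERIC:
            return float(self.value)  # type: ignore[arg-type]
        return float("inf") if self.status == INFINITE else float("nan")

    def __str__(self) -> str:
        if self.status == NUMERIC:
            return str(self.value)
        return "Inf" if self.status == INFINITE else "NA"


@dataclass(frozen=True)
class SRDResult:
    gene_id: str
    metabolite_id: str
    srd: SRDValue
    pathway_id: str


def node_distances(g: MetabolicGraph, source: str) -> dict[str, int]:
    """Unweighted shortest-path distance (edge count) from ``source``.

    Unreachable nodes are absent from the mapping; ``distance[source] == 0``.
    """
    if source not in g.graph:
        raise KeyError(f"source compound {source!r} not in graph")
    return _bfs(g, [source])


def _bfs(g: MetabolicGraph, sources: Iterable[str]) -> dict[str, int]:
    """Multi-source BFS over the multigraph (parallel edges are unit weight)."""
    adj = g.graph.adj
    dist = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def srd(g: MetabolicGraph, gene_id: str, metabolite_id: str) -> SRDValue:
    """SRD of one pair.  Absence is an answer (``NA``), never an error."""
    incident = g.gene_index.get(gene_id)
    if not incident or metabolite_id not in g.graph:
        return SRDValue.not_available()
    if metabolite_id in incident:
        return SRDValue.numeric(0)
    dist = _bfs(g, incident)
    if metabolite_id not in dist:
        return SRDValue.infinite()
    return SRDValue.numeric(dist[metabolite_id])


def srd_batch(
    g: MetabolicGraph, pairs: Sequence[tuple[str, str]]
) -> list[SRDResult]:
    """SRD for many pairs, order-preserving, one BFS per distinct gene.

    Results are identical to calling :func:`srd` pair by pair; grouping by
    gene just avoids repeating the multi-source sweep.
    """
    dist_by_gene: dict[str, dict[str, int] | None] = {}
    out: list[SRDResult] = []
    for gene_id, met_id in pairs:
        if gene_id not in dist_by_gene:
            incident = g.gene_index.get(gene_id)
            dist_by_gene[gene_id] = _bfs(g, incident) if incident else None
        dist = dist_by_gene[gene_id]
        if dist is None or met_id not in g.graph:
            value = SRDValue.not_available()
        elif met_id in dist:
            value = SRDValue.numeric(dist[met_id])
        else:
            value = SRDValue.infinite()
        out.append(SRDResult(gene_id, met_id, value, g.pathway_id))
    return out


def all_pairs_srd_matrix(
    g: MetabolicGraph,
) -> tuple[list[str], list[str], np.ndarray]:
    """SRD for every (gene, metabolite) combination as a dense matrix.

    Returns (genes, metabolites, D) with genes and metabolites sorted and
    ``D[i, j]`` the SRD of gene i to metabolite j; disconnected pairs are
    ``inf``.  ``NA`` cannot occur: both members are in-graph by construction.
    """
    if g.graph.number_of_nodes() == 0:
        raise ValueError("all_pairs_srd: empty graph")
    nodes = g.metabolites()
    genes = g.genes()
    index = {n: i for i, n in enumerate(nodes)}
    # integer adjacency for a fast python BFS at overview-map scale
    adj: list[list[int]] = [[] for _ in nodes]
    simple: list[set[int]] = [set() for _ in nodes]
    for a, b in g.graph.edges():
        ia, ib = index[a], index[b]
        if ib not in simple[ia]:
            simple[ia].add(ib)
            simple[ib].add(ia)
            adj[ia].append(ib)
            adj[ib].append(ia)
    n = len(nodes)
    D = np.full((len(genes), n), np.inf)
    dist = np.empty(n, dtype=np.int32)
    for gi, gene in enumerate(genes):
        dist.fill(-1)
        queue = deque()
        for s in g.gene_index[gene]:
            si = index[s]
            dist[si] = 0
            queue.append(si)
        while queue:
            u = queue.popleft()
            du = dist[u] + 1
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = du
                    queue.append(v)
        reached = dist >= 0
        D[gi, reached] = dist[reached]
    return genes, nodes, D


def all_pairs_srd(g: MetabolicGraph) -> pd.DataFrame:
    """All-pairs SRD as a long table: one row per (gene, metabolite).

    The ``srd`` column is float: finite values are reaction-step counts and
    ``inf`` marks disconnected pairs.  This is the graph-wide null
    distribution of SRD values (|genes| x |metabolites| rows).
    """
    genes, nodes, D = all_pairs_srd_matrix(g)
    n_genes, n_nodes = len(genes), len(nodes)
    return pd.DataFrame(
        {
            "gene_id": pd.Categorical.from_codes(
                np.repeat(np.arange(n_genes), n_nodes), categories=genes
            ),
            "metabolite_id": pd.Categorical.from_codes(
                np.tile(np.arange(n_nodes), n_genes), categories=nodes
            ),
            "pathway_id": g.pathway_id,
            "srd": D.ravel(),
        }
    )
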