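"""Synthetic pathway documents and mGWAS summary statistics with ground truth.

Two generators make the whole toolkit testable offline:

* :func:`generate_pathway` builds a KGML-compatible pathway document of
  chosen topology (chain, random branched, multiple components), optionally
  salted with promiscuous side compounds, and computes the true all-pairs SRD
  table with a Floyd-Warshall oracle that shares no code with the BFS engine.
* :func:`generate_summary_stats` plants a linear effect of SRD on association
  strength: for causal pairs, -log10 p = a - b*SRD + Normal(0, sigma),
  truncated at 0; non-causal SNP-metabolite records draw p ~ Uniform(0, 1).
  Causal pairs are sampled preferentially at low SRD.  This is a synthetic
  convention for testing recovery, not a biological claim — real mGWAS have
  LD structure, correlated metabolites and winner's-curse effects none of
  which are emulated.

Everything is a pure function of (spec, seed): identical specs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

from .kgml import COMPOUND, GENE, Entry, PathwayDocument, Reaction

__all__ = [
    "PathwayGenSpec",
    "MgwasGenSpec",
    "GeneratedPathway",
    "MgwasDataset",
    "generate_pathway",
    "generate_summary_stats",
    "toy_enzyme_neighborhood",
]

CHAIN = "chain"
BRANCHED = "branched_random"
MULTI = "multi_component"


@dataclass(frozen=True)
class PathwayGenSpec:
    """Parameters of a synthetic pathway.

    Defaults give a small connected branched map, roomy enough to exercise
    distances up to ~10 reaction steps while keeping tests fast.
    """

    n_compounds: int = 20
    n_reactions: int = 25
    n_genes: int = 10
    topology: str = BRANCHED
    side_compound_fraction: float = 0.0
    seed: int = 0


@dataclass
class GeneratedPathway:
    """A synthetic pathway plus its independently computed truth.

    ``truth`` holds the oracle SRD for every (gene, compound) pair on the
    graph built with ``side_compounds`` removed: columns gene_id,
    metabolite_id, srd (float; ``inf`` = disconnected).
    """

    document: PathwayDocument
    side_compounds: frozenset[str]
    truth: pd.DataFrame
    spec: PathwayGenSpec


def _compound_id(i: int) -> str:
    return f"C9{i:04d}"


def _gene_id(i: int) -> str:
    return f"hsa:9{i + 1:05d}"


def generate_pathway(spec: PathwayGenSpec, with_truth: bool = True) -> GeneratedPathway:
    """Build a synthetic pathway document with known all-pairs SRD.

    Topologies:

    * ``chain`` — compounds in a line; reaction i converts compound i to
      compound i+1 (requires n_reactions <= n_compounds - 1).
    * ``branched_random`` — a random spanning tree plus extra random
      reactions; occasionally a reaction gains a co-substrate or co-product.
    * ``multi_component`` — two or three disjoint chains/trees, guaranteeing
      infinite SRDs across components.

    Genes are assigned to reactions round-robin so every gene catalyzes at
    least one reaction when n_genes <= n_reactions.  With a positive
    ``side_compound_fraction`` the last compounds become promiscuous side
    compounds appended to many reactions; the truth table is computed on the
    graph *with those side compounds removed*.

    ``with_truth=False`` skips the cubic-time Floyd-Warshall oracle — useful
    when only the document is needed at overview-map scale (thousands of
    compounds); the ``truth`` table is then empty.
    """
    if spec.n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if spec.n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    n_main = spec.n_compounds - int(spec.side_compound_fraction * spec.n_compounds)
    if n_main < 2:
        raise ValueError("side_compound_fraction leaves fewer than 2 main compounds")
    if spec.n_reactions > n_main * (n_main - 1):
        raise ValueError("more reactions than ordered compound pairs")
    rng = np.random.default_rng(spec.seed)

    compounds = [_compound_id(i) for i in range(spec.n_compounds)]
    main = compounds[:n_main]
    side = frozenset(compounds[n_main:])
    genes = [_gene_id(i) for i in range(spec.n_genes)]

    # reaction skeleton: list of (substrate indices, product indices) into main
    skeleton: list[tuple[list[int], list[int]]] = []
    if spec.topology == CHAIN:
        if spec.n_reactions > n_main - 1:
            raise ValueError("chain topology needs n_reactions <= n_compounds - 1")
        skeleton = [([i], [i + 1]) for i in range(spec.n_reactions)]
    elif spec.topology == BRANCHED:
        for i in range(1, min(n_main, spec.n_reactions + 1)):
            parent = int(rng.integers(0, i))
            skeleton.append(([parent], [i]))
        while len(skeleton) < spec.n_reactions:
            a, b = rng.choice(n_main, size=2, replace=False)
            skeleton.append(([int(a)], [int(b)]))
        for subs, prods in skeleton:
            if rng.random() < 0.2:  # co-substrate / co-product
                extra = int(rng.integers(0, n_main))
                (subs if rng.random() < 0.5 else prods).append(extra)
    elif spec.topology == MULTI:
        n_parts = 3 if n_main >= 9 else 2
        bounds = np.linspace(0, n_main, n_parts + 1).astype(int)
        part_edges = []
        for k in range(n_parts):
            lo, hi = bounds[k], bounds[k + 1]
            for i in range(lo + 1, hi):
                parent = int(rng.integers(lo, i))
                part_edges.append(([parent], [i]))
        skeleton = part_edges[: spec.n_reactions]
        if not skeleton:
            raise ValueError("multi_component spec produced no reactions")
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")

    # append side compounds promiscuously (they should create shortcuts that
    # removal then eliminates)
    side_list = sorted(side)
    for subs, prods in skeleton:
        for j, sc in enumerate(side_list):
            if rng.random() < 0.3:
                idx = n_main + side_list.index(sc)
                (subs if j % 2 == 0 else prods).append(idx)

    entries = [Entry(entry_id=f"c{i}", kind=COMPOUND, kegg_ids=(cid,)) for i, cid in enumerate(compounds)]
    entries += [Entry(entry_id=f"g{i}", kind=GENE, kegg_ids=(gid,)) for i, gid in enumerate(genes)]
    reactions = []
    for ri, (subs, prods) in enumerate(skeleton):
        gene_entry = f"g{ri % spec.n_genes}"
        reactions.append(
            Reaction(
                reaction_id=f"R9{ri:04d}",
                substrates=tuple(f"c{i}" for i in dict.fromkeys(subs)),
                products=tuple(f"c{i}" for i in dict.fromkeys(prods)),
                catalysts=(gene_entry,),
                reversible=True,
            )
        )
    doc = PathwayDocument(
        pathway_id=f"syn{spec.seed:05d}",
        title=f"synthetic {spec.topology} pathway",
        entries=tuple(entries),
        reactions=tuple(reactions),
    )
    if with_truth:
        truth = _oracle_truth(doc, side)
    else:
        truth = pd.DataFrame(columns=["gene_id", "metabolite_id", "srd"])
    return GeneratedPathway(document=doc, side_compounds=side, truth=truth, spec=spec)


def _oracle_truth(doc: PathwayDocument, side: frozenset[str]) -> pd.DataFrame:
    """All-pairs gene-to-compound SRD by Floyd-Warshall (oracle, not BFS).

    Re-derives the substrate x product edge expansion from the document and
    runs scipy's dense Floyd-Warshall; the gene SRD is the minimum over the
    gene's incident compounds.  Shares no code with the SRD engine.
    """
    nodes = sorted(
        cid for e in doc.entries if e.kind == COMPOUND for cid in e.kegg_ids if cid not in side
    )
    idx = {c: i for i, c in enumerate(nodes)}
    gene_incident: dict[str, set[int]] = {}
    rows, cols = [], []
    for r in doc.reactions:
        subs = [c for ref in r.substrates for c in doc.entry(ref).kegg_ids if c not in side]
        prods = [c for ref in r.products for c in doc.entry(ref).kegg_ids if c not in side]
        if not subs or not prods:
            continue
        gene_ids = [g for ref in r.catalysts for g in doc.entry(ref).kegg_ids]
        for s in subs:
            for p in prods:
                rows.append(idx[s])
                cols.append(idx[p])
                for gid in gene_ids:
                    gene_incident.setdefault(gid, set()).update((idx[s], idx[p]))
    n = len(nodes)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    D = floyd_warshall(adj, directed=False, unweighted=True)
    records = []
    for gid in sorted(gene_incident):
        dist = D[sorted(gene_incident[gid]), :].min(axis=0)
        for j, cid in enumerate(nodes):
            records.append((gid, cid, float(dist[j])))
    return pd.DataFrame(records, columns=["gene_id", "metabolite_id", "srd"])


def toy_enzyme_neighborhood() -> PathwayDocument:
    """The canonical worked example: one enzyme and its reaction neighborhood.

    Enzyme A catalyzes substrate -> product.  Both reactants are at SRD 0
    from A; each further reaction adds one step: the metabolites one reaction
    beyond the substrate or product sit at SRD 1, and the metabolite one more
    reaction out sits at SRD 2.

    Layout (compound / catalyzing gene):

    .. code-block:: text

        C00010 (up1) --E3-- C00001 (substrate) ==A== C00002 (product)
                                                       |E1        |E2
                                             C00011 (down1) C00012 (down1b)
                                                       |E4
                                             C00021 (down2)
    """
    entries = (
        Entry("1", COMPOUND, ("C00001",)),  # substrate of A
        Entry("2", COMPOUND, ("C00002",)),  # product of A
        Entry("3", COMPOUND, ("C00010",)),  # one step before the substrate
        Entry("4", COMPOUND, ("C00011",)),  # one step past the product
        Entry("5", COMPOUND, ("C00012",)),  # one step past the product
        Entry("6", COMPOUND, ("C00021",)),  # two steps out
        Entry("10", GENE, ("hsa:100",)),  # enzyme A
        Entry("11", GENE, ("hsa:101",)),
        Entry("12", GENE, ("hsa:102",)),
        Entry("13", GENE, ("hsa:103",)),
        Entry("14", GENE, ("hsa:104",)),
    )
    reactions = (
        Reaction("R0001", substrates=("1",), products=("2",), catalysts=("10",)),
        Reaction("R0002", substrates=("3",), products=("1",), catalysts=("11",)),
        Reaction("R0003", substrates=("2",), products=("4",), catalysts=("12",)),
        Reaction("R0004", substrates=("2",), products=("5",), catalysts=("13",)),
        Reaction("R0005", substrates=("4",), products=("6",), catalysts=("14",)),
    )
    return PathwayDocument(
        pathway_id="toy00001",
        title="enzyme neighborhood worked example",
        entries=entries,
        reactions=reactions,
    )


@dataclass(frozen=True)
class MgwasGenSpec:
    """Parameters of the planted-effect summary-statistics generator.

    The effect model for a causal pair with shortest reactional distance d is
    ``-log10 p = a - b*d + Normal(0, sigma)`` truncated at 0.  Defaults
    (a=10, b=1, sigma=1) put SRD-0 causal pairs at genome-wide significance
    and let significance decay by one order of magnitude per reaction step —
    a stylized version of the negative SRD-significance relationship the
    annotation is designed to detect.
    """

    n_snps_per_gene: int = 3
    n_metabolites: int | None = None
    a: float = 10.0
    b: float = 1.0
    sigma: float = 1.0
    causal_fraction: float = 0.1
    seed: int = 0


@dataclass
class MgwasDataset:
    summary_stats: pd.DataFrame
    intervals: pd.DataFrame
    causal_pairs: pd.DataFrame
    spec: MgwasGenSpec
    metabolites: list[str] = field(default_factory=list)


def generate_summary_stats(
    pathway: GeneratedPathway, spec: MgwasGenSpec
) -> MgwasDataset:
    """Synthesize long-format summary statistics over a generated pathway.

    Every truth-table gene gets a non-overlapping interval on the synthetic
    chromosome ``chrS1`` with ``n_snps_per_gene`` SNPs inside the gene body
    (hence within any >=0 flank).  Causal pairs are drawn without replacement
    from the finite-SRD (gene, metabolite) pairs with probability weights
    ``exp(-SRD / 8)`` (preferring short distances); the causal p value is
    planted on the gene's first SNP.  All records are biallelic with MAF
    uniform on (0.011, 0.5).
    """
    truth = pathway.truth
    genes = sorted(truth["gene_id"].unique())
    all_mets = sorted(truth["metabolite_id"].unique())
    rng = np.random.default_rng(spec.seed)
    if spec.n_metabolites is None or spec.n_metabolites >= len(all_mets):
        mets = all_mets
    else:
        mets = sorted(rng.choice(all_mets, size=spec.n_metabolites, replace=False))

    # gene intervals: 20 kb bodies spaced 200 kb apart -> windows overlap only
    # at large flanks, giving the flank-superset behaviour real data shows
    intervals = pd.DataFrame(
        {
            "chrom": "chrS1",
            "start": [1_000_000 + 200_000 * i for i in range(len(genes))],
            "end": [1_020_000 + 200_000 * i for i in range(len(genes))],
            "name": [f"iv{i}" for i in range(len(genes))],
            "score": 0,
            "strand": "+",
            "gene_symbol": [f"SYNG{i + 1}" for i in range(len(genes))],
            "kegg_gene_id": genes,
        }
    )

    srd_lookup = {
        (r.gene_id, r.metabolite_id): r.srd for r in truth.itertuples(index=False)
    }
    finite_pairs = [
        (gn, m) for gn in genes for m in mets if np.isfinite(srd_lookup.get((gn, m), np.inf))
    ]
    n_causal = min(
        len(finite_pairs), int(round(spec.causal_fraction * len(genes) * len(mets)))
    )
    causal: list[tuple[str, str]] = []
    if n_causal and spec.causal_fraction > 0:
        # preference for short distances scales with the planted effect b:
        # b = 0 plants no SRD structure at all, so sampling is uniform then
        weights = np.array([np.exp(-spec.b * srd_lookup[p] / 8.0) for p in finite_pairs])
        pick = rng.choice(len(finite_pairs), size=n_causal, replace=False, p=weights / weights.sum())
        causal = [finite_pairs[i] for i in sorted(pick)]
    causal_set = set(causal)

    snp_rows = []
    for i, gene in enumerate(genes):
        start = int(intervals.loc[i, "start"])
        for s in range(spec.n_snps_per_gene):
            snp_rows.append(
                {
                    "CHROM": "chrS1",
                    "POS": start + 1_000 + 2_000 * s + 1,  # 1-based, inside body
                    "A1": "A",
                    "A2": "C",
                    "MAF": float(rng.uniform(0.011, 0.5)),
                    "gene": gene,
                    "snp_rank": s,
                }
            )
    snps = pd.DataFrame(snp_rows)

    records = []
    causal_records = []
    for row in snps.itertuples(index=False):
        for m in mets:
            is_causal = row.snp_rank == 0 and (row.gene, m) in causal_set
            if is_causal:
                d = srd_lookup[(row.gene, m)]
                y = max(spec.a - spec.b * d + rng.normal(0.0, spec.sigma), 0.0)
                p = max(10.0 ** -y, 1e-300)
                causal_records.append(
                    {
                        "kegg_gene_id": row.gene,
                        "metabolite_key": m,
                        "srd": d,
                        "planted_p": p,
                    }
                )
            else:
                p = float(rng.uniform(0.0, 1.0)) or 1e-12
            records.append(
                {
                    "CHROM": row.CHROM,
                    "POS": row.POS,
                    "A1": row.A1,
                    "A2": row.A2,
                    "METABOLITE": m,
                    "P": p,
                    "MAF": row.MAF,
                }
            )
    summary = pd.DataFrame(records, columns=["CHROM", "POS", "A1", "A2", "METABOLITE", "P", "MAF"])
    causal_df = pd.DataFrame(
        causal_records, columns=["kegg_gene_id", "metabolite_key", "srd", "planted_p"]
    )
    return MgwasDataset(
        summary_stats=summary,
        intervals=intervals,
        causal_pairs=causal_df,
        spec=spec,
        metabolites=list(mets),
    )
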