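# srdkit

Annotating gene–metabolite associations with shortest reactional distances
on KEGG-style metabolic pathway graphs.

## The problem

Metabolite genome-wide association studies (mGWAS) produce long lists of
SNP–metabolite associations. After mapping SNPs to candidate genes, each
gene–metabolite pair carries only a p value — no statement about whether the
gene's enzymatic function has anything to do with the metabolite. `srdkit`
adds that statement: it converts a metabolic pathway map into an undirected
graph with **metabolites as nodes and genes as edge labels**, and annotates
every pair with its **shortest reactional distance (SRD)** — the minimum
number of reaction steps between the metabolite and the gene's own
reactants:

* `SRD = 0`: the metabolite is a substrate or product of a reaction the
  gene catalyzes; each further reaction adds 1;
* `Inf`: gene and metabolite are both in the graph but disconnected;
* `NA`: the gene or the metabolite is absent from the queried graph, even
  with a valid KEGG ID.

Formally, for gene *g* with incident node set *N(g)* (the substrates and
products of its reactions) and metabolite *m*,

```
SRD(g, m) = min_{v in N(g)} d(v, m)
```

with *d* the unweighted shortest-path length (breadth-first search; with
unit weights BFS and Dijkstra coincide). Small SRDs among significant pairs
indicate biologically close associations; pairs with suggestive p values
but small SRDs are candidate false negatives worth a second look.

The package is aimed at statistical geneticists and systems biologists
post-processing mGWAS summary statistics, and at anyone who needs reactional
distances on KEGG pathway graphs.

## What it does

* **`srdkit.kgml`** — parse, validate, merge and write KGML pathway XML;
  cache-first KEGG retrieval helper (tests never touch the network).
* **`srdkit.graph`** — substrate×product reaction-graph construction with
  optional side-compound (ATP, H2O, ...) removal to eliminate cofactor
  shortcuts; graph summaries.
* **`srdkit.srd`** — three-valued SRD for single pairs, batches, and all
  |genes|×|metabolites| combinations (millions of pairs in seconds).
* **`srdkit.mgwas`** — summary-statistics QC (biallelic, MAF > 0.01,
  completeness), SNP→gene mapping by flanked genomic interval or eQTL
  evidence, minimum-p aggregation per pair, significance categories
  (R / S+ / S− / NS), QQ-plot cutoff heuristic.
* **`srdkit.idmap`** — offline, table-driven ID resolution (gene symbol /
  metabolite name → KEGG ID) with the acylcarnitine→acyl-CoA proxy
  mechanism; every substitution is flagged.
* **`srdkit.stats`** — graph-wide null distribution, first-quartile "small
  SRD" threshold, permutation test on the median SRD, Welch comparison,
  SRD–significance correlation with graph-aware empirical p values.
* **`srdkit.reporting`** — annotated pair tables (SRD serialized as
  integer/`Inf`/`NA`, proxies marked `*`), gene×metabolite SRD heatmaps,
  category frequency plots; every figure writes a numeric sidecar.
* **`srdkit.synth`** — synthetic KGML pathways (chains, branched maps,
  disconnected components, side compounds) with an independent
  Floyd–Warshall ground truth, and synthetic mGWAS summary statistics with
  a planted SRD→significance effect.

There is no command-line interface: the importable API is the interface,
and `examples/` holds one short runnable script per capability.

## Worked example

`examples/01_toy_srd.py` builds one enzyme's reaction neighborhood and
prints:

```
SRD from the enzyme to each metabolite (reaction steps):
  C00001 (its substrate): SRD = 0
  C00002 (its product): SRD = 0
  C00010 (one reaction before the substrate): SRD = 1
  C00011 (one reaction past the product): SRD = 1
  C00012 (one reaction past the product): SRD = 1
  C00021 (two reactions out): SRD = 2
  unknown gene hsa:999 vs C00001: SRD = NA
```

The enzyme's own reactants are at distance 0; every additional reaction
adds one step; a gene or metabolite missing from the graph yields `NA`
rather than an error.

`examples/04_null_statistics.py` runs the inferential layer on a synthetic
chain pathway with 200 planted causal pairs:

```
null distribution: 2000 finite SRDs, 0 infinite
null median 6, first quartile threshold 3
observed median SRD: 4.0
permutation empirical p (n_perm=1000, seed=1): 0.001998
Welch vs null: t=-7.132, p=9e-12
SRD vs -log10(p) correlation: r=-0.947, parametric p=6.58e-100, empirical p=0.000999
```

The observed pairs sit closer than random gene–metabolite pairing (median 4
vs 6, empirical p ≈ 0.002), and association strength falls off with
reactional distance (negative correlation, empirical p at its
1/(n_perm+1) floor).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the worked-example pathway from KGML text and recomputes, from
scratch, the SRD from the enzyme to its direct reactants, to the
metabolites one reaction beyond them, and to the metabolite two reactions
out, writing the values as JSON.

## Caveats

KEGG map content drifts across releases: quantities derived from a specific
overview-map version (null quartiles, pair counts) are reproducible only
against the same KGML file, which is why the fetch helper records the
retrieval date and all tests run on generated fixtures. See
`docs/methods.md` for the model, conventions and limitations.
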