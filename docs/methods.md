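# Methods

## The graph model

A pathway document (KGML) is converted to an undirected multigraph:
compound entries become nodes, and every reaction with substrate set *S*,
product set *P* and catalyst genes *G* contributes one edge (s, p) labelled
*G* for each s ∈ S, p ∈ P.

Conventions, and why:

* **Substrate×product expansion only.** No substrate–substrate or
  product–product edges: the enzyme edge joins what is consumed to what is
  produced. Pairwise-all expansion would let co-substrates (e.g. ATP in any
  kinase reaction) create shortcuts between unrelated branches.
* **Undirected, unweighted.** KEGG maps do not carry reliable reaction
  directionality, and the SRD metric counts reaction steps, not flux.
  Reversibility flags are parsed and preserved but ignored by the metric.
* **Parallel edges are kept** (same node pair, different reaction), so a
  gene's incident node set is exactly the union over all its reactions.
* **Uncatalyzed reactions contribute unlabelled edges.** Metabolite–
  metabolite connectivity should reflect the whole network even where no
  gene is annotated; such edges carry an empty gene set.
* **Side compounds** (ATP, H2O, NAD(P)H, CoA, Pi, ... — a packaged,
  editable list) can be removed at build time. Removal deletes their nodes
  and all edges through them; a reaction whose non-side substrate or
  product set becomes empty contributes nothing. Removal is opt-in:
  whether cofactor shortcuts are signal or noise depends on the question.
  Removing a node can only lengthen (or disconnect) remaining paths — this
  shortcut-elimination property is asserted in the tests.
* Entries of KGML type `ortholog` or `group` are retained in the document
  model as kind `other` but excluded from graph construction; glycan IDs
  (`gl:`) count as compounds. An entry carrying several gene IDs yields one
  entry whose genes all catalyze its reactions.

## The SRD metric

SRD(g, m) = min over the gene's incident nodes v of d(v, m), computed by a
multi-source BFS from the incident set (unit weights: BFS ≡ Dijkstra).
Outcomes are three-valued: a non-negative integer; `Inf` when both members
are in-graph but no path exists; `NA` when the gene or metabolite is not in
the queried graph at all. `NA` takes precedence over `Inf` when both could
apply. Reports serialize these as the integer, `"Inf"`, `"NA"`.

A gene with several reactions minimizes over all of them — "shortest"
semantics. SRD(g, m) = 0 iff m is a substrate or product of some retained
reaction of g. For finite values the metric obeys an edge-to-node triangle
inequality |SRD(g,m1) − SRD(g,m2)| ≤ d(m1,m2), and adding edges never
increases a finite SRD; both are property-tested.

The all-pairs run (needed for null distributions) uses one multi-source BFS
per gene over an integer-indexed adjacency, so overview-map scale
(1,351 genes × 2,889 metabolites = 3,903,039 pairs) takes seconds.

## The annotation pipeline

1. **QC**: keep biallelic SNVs (single-base, distinct alleles; indels and
   multi-allelic records only under a flag), MAF strictly > 0.01, tested
   for all (configurable: a fraction of) the study's metabolites.
   Exclusion counts per filter are logged and attached to the result.
2. **SNP→gene**: a SNP links to *every* enzyme-coding gene whose interval,
   extended symmetrically by the flank (default 10 kb; 50 kb–1 Mb for
   sensitivity analyses), contains it. Intervals are BED-style 0-based
   half-open; summary-statistic positions are 1-based and converted at the
   boundary, so containment is `start − flank ≤ pos − 1 < end + flank`.
   "All genes in the window" rather than "nearest gene" is deliberate: it
   reproduces multi-gene loci and keeps the flank-superset property
   (widening the flank can only add links). An eQTL route (FDR ≤ 0.05 by
   default) is available; pairs found by both routes record both sources.
3. **Aggregation**: per (gene, metabolite) pair only the minimum p over all
   contributing SNPs is kept, with the achieving SNP; ties break by
   (chrom, pos, alleles) so output is reproducible.
4. **Categories**: R (p below the genome-wide cutoff, by default a
   Bonferroni base of 1e-7 divided by the number of metabolites — 128
   metabolites give 7.8125e-10), S+ (up to 1e-7), S− (up to the pair-level
   cutoff, default 3.16e-5), NS otherwise. Inequalities are strict;
   boundary values fall into the less significant band.

The pair-level cutoff is in practice chosen graphically from a QQ plot.
`qqplot_cutoff` automates one reading of that: scanning from the null end,
it flags the first point where the secant slope of observed vs expected
−log10 quantiles over a trailing window (default 50 points) exceeds twice
the cumulative slope before it. Pointwise order-statistic slopes are far
too noisy for this comparison; the windowed secant and cumulative baseline
average the noise away. The heuristic is advisory — it always returns the
full quantile table for a human override, and the packaged defaults keep
user-supplied cutoffs authoritative.

## ID mapping

All resolution is offline and table-driven (3-column TSV: source key, KEGG
ID, kind). Normalization is deliberately conservative — lowercase,
whitespace collapse, unicode-dash folding, no fuzzy matching — because a
reported unresolved key is recoverable and a silent mismatch is not.
Metabolites without any KEGG entry but with a close chemical counterpart
(acylcarnitines → acyl-CoA) can be substituted through `proxy` rows; a
direct mapping always wins, every substitution is logged, and proxied
metabolites carry a `*` marker through to the reports. Substitution is
idempotent.

## Inference

* **Null distribution**: SRD of every gene×metabolite combination in the
  graph; finite values and the `Inf` count are reported separately (`NA`
  cannot occur — both members are in-graph by construction).
* **Small-SRD threshold**: the first quartile of the finite null values,
  type-7 (linear interpolation) quantile floored to an integer. The
  quantile type is pinned here because integer-exact thresholds on real
  maps depend on it; no claim is made that other quantile definitions give
  the same integer.
* **Permutation test on the median**: each permutation keeps every pair's
  gene and reassigns its metabolite within the observed metabolite set —
  by default sampling uniformly with replacement from the distinct observed
  metabolites (`resample`), alternatively permuting the observed metabolite
  column (`shuffle`, the exchangeable variant). Medians are taken over
  finite SRDs only, mirroring how observed pair sets are summarized.
  Empirical p = (1 + #{perm ≤ obs}) / (n_perm + 1): never exactly zero.
* **Welch test**: observed finite SRDs vs the null values, unequal
  variances, Satterthwaite degrees of freedom, two-sided.
* **SRD–significance correlation**: Pearson r (Spearman optional) between
  SRD and −log10(min p) on finite-SRD pairs, optionally restricted to pairs
  below the pair-level cutoff. The parametric p assumes independence the
  shared graph structure violates, so an empirical p is computed from the
  same permutation schemes, recomputing SRD and r per permutation, with the
  negative-correlation alternative. Constant SRD across pairs is reported
  as not-computable rather than erroring mid-pipeline.

All stochastic routines are pure functions of (seed, n_perm).

### Calibration notes

Under the `shuffle` scheme the observed statistic is exchangeable with the
permuted ones, so the empirical p is uniform up to the discreteness of the
statistic. For the *median* of a handful of integer SRDs that discreteness
is substantial on compact graphs: the permutation distribution of the
median concentrates on very few values and the p values become
conservative (stochastically larger than uniform). The calibration tests
therefore run on a long chain, where the SRD support is wide and the
median of nine pairs takes many values; on dense graphs the conservatism
is inherent to a tied median, not an implementation artifact. The
correlation statistic is effectively continuous and calibrates on any
fixture. The `resample` scheme is only approximately exchangeable; it is
the default for its interpretability (random re-pairing within the
observed sets), with `shuffle` available wherever exactness matters.

## The synthetic generators

`generate_pathway` emits KGML-compatible documents with known topology —
`chain` (distances are position gaps, closed form), `branched_random`
(random spanning tree plus extra reactions, occasional co-substrates),
`multi_component` (guaranteed `Inf` pairs) — optionally salted with
promiscuous side compounds. Ground truth for all (gene, metabolite) pairs
is computed by scipy's Floyd–Warshall on an independently re-derived
adjacency, sharing no code with the BFS engine; at overview-map scale the
cubic oracle can be skipped (`with_truth=False`).

`generate_summary_stats` plants the effect the annotation is designed to
detect: for a causal pair at distance d, −log10 p = a − b·d +
Normal(0, σ), truncated at 0; non-causal records draw p ~ Uniform(0, 1).
Defaults a = 10, b = 1, σ = 1 put distance-0 causal pairs at genome-wide
significance with one order of magnitude lost per reaction step. Causal
pairs are sampled with weight exp(−b·d/8), so the low-SRD preference
scales with the planted effect and vanishes at b = 0 (the null generator).
Each gene gets a 20 kb interval on a synthetic chromosome (`chrS1`),
spaced 200 kb apart so flank widening genuinely absorbs neighboring SNPs,
with 3 SNPs inside the gene body; all records biallelic, MAF uniform on
(0.011, 0.5).

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, correlated metabolites, winner's curse, or any
real metabolic topology. A green recovery test establishes that the
pipeline recovers the planted linear-in-SRD effect under clean conditions —
not that real mGWAS effects are linear in SRD, nor anything about a
specific KEGG release.

## Numerical and degenerate-input choices

* Empirical p values use (1+k)/(1+n); permutations with no finite SRD get
  an infinite median (never ≤ observed).
* Welch on two degenerate (zero-variance) samples raises; identical
  samples give t = 0, p = 1.
* `quartile_threshold` requires ≥ 4 finite values; `qqplot_cutoff`
  requires ≥ 100 p values; correlation requires ≥ 10 finite-SRD pairs.
* Merging pathways deduplicates entries by (kind, KEGG ID set) and
  reactions by (reaction ID, reactant KEGG ID sets); document equality is
  judged on a canonical form invariant to entry numbering and order.
* Figures render on the Agg backend at fixed DPI with alphabetical axis
  ordering, so re-rendering identical inputs is byte-identical; `Inf` and
  `NA` cells use reserved colors (gray / white) outside the numeric ramp.

## Known limitations

* No reaction directionality, stoichiometry, compartments, or SBML input.
* KEGG content drifts across releases: counts and quartiles derived from a
  live download are tied to the retrieval date recorded by the fetch
  helper; no historical-version reconstruction is attempted.
* The nearest-gene alternative to all-in-window SNP mapping is not
  implemented.
* No multiple-testing control across statistical reports at this layer.
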