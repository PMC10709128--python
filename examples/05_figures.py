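"""Presentation artifacts: the SRD heatmap and the category frequency plot.

Annotates a small synthetic study, draws the gene x metabolite SRD heatmap
with the significant pairs boxed, and the per-category frequencies of
small (<= threshold) SRD values.  Every figure writes its numbers to a
sidecar .tsv so the plotted values remain on record.
"""

from srdkit import (
    aggregate_min_p,
    build_graph,
    category_frequency_plot,
    classify_significance,
    map_snps_to_genes,
    qc_filter,
    srd_batch,
    srd_heatmap,
)
from srdkit.synth import MgwasGenSpec, PathwayGenSpec, generate_pathway, generate_summary_stats

gp = generate_pathway(
    PathwayGenSpec(n_compounds=24, n_reactions=30, n_genes=8, topology="branched_random", seed=13)
)
g = build_graph(gp.document, gp.side_compounds)
ds = generate_summary_stats(gp, MgwasGenSpec(seed=13, n_metabolites=12, causal_fraction=0.2))

records = qc_filter(ds.summary_stats)
pairs = aggregate_min_p(map_snps_to_genes(records, ds.intervals, 10_000), records)
pairs = classify_significance(pairs, n_metabolites=len(ds.metabolites))
pairs["srd"] = [
    r.srd.as_float()
    for r in srd_batch(g, list(zip(pairs["kegg_gene_id"], pairs["metabolite_key"])))
]
pairs["kegg_metabolite_id"] = pairs["metabolite_key"]

significant = set(
    zip(
        pairs.loc[pairs["category"] != "NS", "kegg_gene_id"],
        pairs.loc[pairs["category"] != "NS", "kegg_metabolite_id"],
    )
)
mat = srd_heatmap(pairs, "srd_heatmap.png", highlight=significant)
print(f"heatmap: {mat.shape[0]} genes x {mat.shape[1]} metabolites, "
      f"{len(significant)} highlighted pairs -> srd_heatmap.png (+ .tsv)")

table = category_frequency_plot(pairs, "category_frequencies.png", threshold=2)
print("category frequencies -> category_frequencies.png (+ .tsv):")
print(table.to_string(index=False))
print()
print("pct_small is the share of finite-SRD pairs at or below the threshold;")
print("infinite/NA outcomes are tallied separately, never averaged in.")
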