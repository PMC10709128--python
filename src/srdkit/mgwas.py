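"""From mGWAS summary statistics to categorized gene-metabolite pairs.

The stage mirrors a standard metabolite-GWAS post-processing pipeline:

1. quality control: keep biallelic SNPs with MAF > 0.01 that were tested
   across all measured metabolites;
2. SNP -> gene mapping, either by genomic interval (every enzyme-coding gene
   whose span extended by a symmetric flank contains the SNP) or by eQTL
   evidence at a chosen FDR;
3. per (gene, metabolite) pair, keep only the minimum p value over all
   contributing SNPs;
4. categorize each pair by significance band: R (genome-wide), S+ and S-
   (upper/lower suggestive), NS.

Canonical input is long format: one row per SNP x metabolite with columns
CHROM, POS (1-based), A1, A2, METABOLITE, P, MAF.  Gene intervals use
BED-style 0-based half-open coordinates; summary-stat positions are converted
at the boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUMMARY_COLUMNS",
    "read_summary_stats",
    "read_per_metabolite_files",
    "read_gene_intervals",
    "load_brite_enzymes",
    "snp_keys",
    "qc_filter",
    "map_snps_to_genes",
    "map_snps_via_eqtl",
    "aggregate_min_p",
    "classify_significance",
    "qqplot_cutoff",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["CHROM", "POS", "A1", "A2", "METABOLITE", "P", "MAF"]
CATEGORIES = ["R", "S_plus", "S_minus", "NS"]

_SNP_COLS = ["CHROM", "POS", "A1", "A2"]


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read long-format summary statistics (tab-delimited, header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing required columns: {missing}")
    return df


def read_per_metabolite_files(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Normalize METAL-style per-metabolite files into the long format.

    ``paths`` maps the study-local metabolite key to a tab-delimited file with
    columns CHROM, POS, A1, A2, P, MAF (one association scan per metabolite).
    """
    frames = []
    for met, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
        df["METABOLITE"] = met
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[SUMMARY_COLUMNS + [c for c in out.columns if c not in SUMMARY_COLUMNS]]


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene intervals: BED6-compatible plus gene symbol and KEGG ID.

    Columns: chrom, start, end, name, score, strand, gene_symbol,
    kegg_gene_id (tab-delimited, no header, '#' comments).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "gene_symbol", "kegg_gene_id"],
        dtype={"chrom": str},
    )
    return df


def load_brite_enzymes(path: str | Path) -> frozenset[str]:
    """Read the enzyme gene list (one KEGG gene ID per line, '#' comments)."""
    ids = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return frozenset(ids)


def snp_keys(df: pd.DataFrame) -> pd.Series:
    """Canonical SNP key: CHROM_POS_A1_A2."""
    return (
        df["CHROM"].astype(str)
        + "_"
        + df["POS"].astype(str)
        + "_"
        + df["A1"].astype(str)
        + "_"
        + df["A2"].astype(str)
    )


def qc_filter(
    records: pd.DataFrame,
    maf_min: float = 0.01,
    completeness: float = 1.0,
    keep_indels: bool = False,
) -> pd.DataFrame:
    """Quality-control filter on summary-statistic records.

    Keeps biallelic SNVs (single-base, distinct alleles; indels and
    multi-allelic records pass only under ``keep_indels``), with strictly
    ``MAF > maf_min``, whose variant was tested for at least ``completeness``
    of the study's metabolites (1.0 = all of them).  Exclusion counts per
    filter are logged and attached as ``.attrs['qc_counts']``.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"qc_filter: missing required columns: {missing}")
    df = records.copy()
    key = snp_keys(df)

    if "N_ALLELES" in df.columns:
        biallelic = df["N_ALLELES"] == 2
    else:
        a1, a2 = df["A1"].astype(str), df["A2"].astype(str)
        biallelic = (a1.str.len() == 1) & (a2.str.len() == 1) & (a1 != a2)
    if keep_indels:
        biallelic = pd.Series(True, index=df.index)

    maf_ok = df["MAF"] > maf_min

    n_metabolites = df["METABOLITE"].nunique()
    per_variant = df.groupby(key.values)["METABOLITE"].nunique()
    complete_keys = per_variant[per_variant >= completeness * n_metabolites].index
    complete = key.isin(complete_keys)

    counts = {
        "input_records": len(df),
        "excluded_not_biallelic": int((~biallelic).sum()),
        "excluded_maf": int((biallelic & ~maf_ok).sum()),
        "excluded_incomplete": int((biallelic & maf_ok & ~complete).sum()),
    }
    out = df[biallelic & maf_ok & complete].copy()
    counts["retained_records"] = len(out)
    for name, n in counts.items():
        logger.info("qc_filter %s: %d", name, n)
    out.attrs["qc_counts"] = counts
    return out


def map_snps_to_genes(
    records: pd.DataFrame,
    intervals: pd.DataFrame,
    flank_bp: int = 10_000,
    enzyme_genes: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Link each SNP to every enzyme gene whose flanked span contains it.

    A SNP at 1-based position ``pos`` (0-based ``pos - 1``) links to a gene
    with 0-based half-open span [start, end) iff
    ``start - flank_bp <= pos - 1 < end + flank_bp``.  The flank is symmetric;
    strand is ignored.  One SNP may link to several overlapping genes.

    ``enzyme_genes`` restricts the intervals to enzyme-coding genes (KEGG
    Brite enzyme subset); ``None`` keeps all intervals.
    """
    snp = records[_SNP_COLS].drop_duplicates().reset_index(drop=True)
    iv = intervals
    if enzyme_genes is not None:
        iv = iv[iv["kegg_gene_id"].isin(enzyme_genes)]

    rec_chroms = set(snp["CHROM"].astype(str))
    iv_chroms = set(iv["chrom"].astype(str))
    if rec_chroms and iv_chroms and not (rec_chroms & iv_chroms):
        raise ValueError(
            "chromosome naming mismatch between summary statistics and gene "
            f"intervals: records use {sorted(rec_chroms)}, intervals use "
            f"{sorted(iv_chroms)}"
        )

    out = []
    for chrom, snps in snp.groupby("CHROM", sort=True):
        sub = iv[iv["chrom"].astype(str) == str(chrom)]
        if sub.empty:
            continue
        pos0 = snps["POS"].to_numpy() - 1
        lo = sub["start"].to_numpy() - flank_bp
        hi = sub["end"].to_numpy() + flank_bp
        hit = (pos0[:, None] >= lo[None, :]) & (pos0[:, None] < hi[None, :])
        si, gi = np.nonzero(hit)
        if len(si) == 0:
            continue
        linked = snps.iloc[si].reset_index(drop=True)
        linked["gene_symbol"] = sub["gene_symbol"].to_numpy()[gi]
        linked["kegg_gene_id"] = sub["kegg_gene_id"].to_numpy()[gi]
        out.append(linked)
    cols = _SNP_COLS + ["gene_symbol", "kegg_gene_id", "mapping_source"]
    if not out:
        return pd.DataFrame(columns=cols)
    links = pd.concat(out, ignore_index=True)
    links["mapping_source"] = "interval"
    return links[cols]


def map_snps_via_eqtl(
    records: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Link SNPs to genes through eQTL evidence at ``fdr <= fdr_max``.

    ``eqtl_table`` columns: snp_key (CHROM_POS_A1_A2), gene_symbol, fdr.
    ``gene_table`` provides the gene_symbol -> kegg_gene_id translation
    (e.g. the interval table); unknown symbols are logged and skipped.
    """
    for col in ("snp_key", "gene_symbol", "fdr"):
        if col not in eqtl_table.columns:
            raise ValueError(f"eqtl table missing column {col!r}")
    sym2kegg = dict(
        zip(gene_table["gene_symbol"].astype(str), gene_table["kegg_gene_id"].astype(str))
    )
    hits = eqtl_table[eqtl_table["fdr"] <= fdr_max].copy()
    unknown = sorted(set(hits["gene_symbol"]) - set(sym2kegg))
    if unknown:
        logger.warning("map_snps_via_eqtl: skipping unknown gene symbols %s", unknown)
        hits = hits[~hits["gene_symbol"].isin(unknown)]

    snp = records[_SNP_COLS].drop_duplicates().copy()
    snp["snp_key"] = snp_keys(snp)
    links = snp.merge(hits[["snp_key", "gene_symbol"]], on="snp_key", how="inner")
    links["kegg_gene_id"] = links["gene_symbol"].map(sym2kegg)
    links["mapping_source"] = "eqtl"
    return links[_SNP_COLS + ["gene_symbol", "kegg_gene_id", "mapping_source"]]


def aggregate_min_p(links: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """One row per (gene, metabolite): the minimum p over contributing SNPs.

    The achieving SNP is recorded; ties on p are broken by (CHROM, POS, A1,
    A2) lexicographic order so the output is reproducible.  Links found by
    several mapping routes collapse to one pair with all sources recorded
    (semicolon-joined).
    """
    merged = links.merge(records, on=_SNP_COLS, how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "kegg_gene_id",
                "gene_symbol",
                "metabolite_key",
                "min_p",
                "best_snp",
                "mapping_source",
            ]
        )
    merged = merged.sort_values(
        ["P", "CHROM", "POS", "A1", "A2"], kind="mergesort"
    ).reset_index(drop=True)
    merged["snp_key"] = snp_keys(merged)
    grouped = merged.groupby(["kegg_gene_id", "METABOLITE"], sort=True)
    best = grouped.first().reset_index()
    sources = (
        grouped["mapping_source"]
        .agg(lambda s: ";".join(sorted(set(s))))
        .reset_index(drop=True)
    )
    out = pd.DataFrame(
        {
            "kegg_gene_id": best["kegg_gene_id"],
            "gene_symbol": best["gene_symbol"],
            "metabolite_key": best["METABOLITE"],
            "min_p": best["P"],
            "best_snp": best["snp_key"],
            "mapping_source": sources,
        }
    )
    return out


def classify_significance(
    pairs: pd.DataFrame,
    n_metabolites: int | None = None,
    genomewide_p: float | None = None,
    genomewide_base: float = 1e-7,
    suggestive_p: float = 1e-7,
    pairlevel_p: float = 3.16e-5,
) -> pd.DataFrame:
    """Assign each pair a significance category by its minimum p value.

    The genome-wide cutoff is ``genomewide_p`` when supplied, otherwise the
    Bonferroni-style ``genomewide_base / n_metabolites`` (e.g. 1e-7 / 128 =
    7.8125e-10).  Bands use strict inequalities; a p value exactly on a
    boundary falls into the less significant category:

    * R:  p < genome-wide cutoff
    * S+: genome-wide cutoff <= p < suggestive_p
    * S-: suggestive_p <= p < pairlevel_p
    * NS: otherwise
    """
    if genomewide_p is None:
        if n_metabolites is None:
            raise ValueError("supply genomewide_p or n_metabolites")
        genomewide_p = genomewide_base / n_metabolites
    if not (genomewide_p < suggestive_p < pairlevel_p):
        raise ValueError(
            "thresholds must satisfy genome-wide < suggestive < pair-level: "
            f"{genomewide_p} < {suggestive_p} < {pairlevel_p} fails"
        )
    p = pairs["min_p"].to_numpy()
    category = np.select(
        [p < genomewide_p, p < suggestive_p, p < pairlevel_p],
        ["R", "S_plus", "S_minus"],
        default="NS",
    )
    out = pairs.copy()
    out["category"] = pd.Categorical(category, categories=CATEGORIES)
    out.attrs["thresholds"] = {
        "genomewide_p": genomewide_p,
        "suggestive_p": suggestive_p,
        "pairlevel_p": pairlevel_p,
    }
    return out


def qqplot_cutoff(
    p_values: Sequence[float] | np.ndarray,
    slope_factor: float = 2.0,
    window: int = 50,
) -> tuple[float | None, pd.DataFrame]:
    """Suggest a suggestive-significance cutoff from QQ-plot slope deflection.

    Builds expected vs observed -log10 quantiles and scans from the null
    (least significant) end for the first point where the local slope — the
    secant of observed against expected over the trailing ``window`` points —
    exceeds ``slope_factor`` times the cumulative slope of everything before
    that window.  Pointwise slopes of order statistics are far too noisy for
    this comparison; both the windowed secant and the cumulative baseline
    average that noise away.  Returns ``(threshold_p, table)``; the threshold
    is ``None`` when no deflection is found.  The full quantile table is
    always returned so the choice can be overridden by eye — the decision is
    ultimately graphical.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    if n < 100:
        raise ValueError(f"qqplot_cutoff needs >=100 p values, got {n}")
    observed = -np.log10(p)  # descending
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    table = pd.DataFrame({"expected": expected, "observed": observed, "p": p})

    window = min(window, n // 5)
    exp_a, obs_a = expected[::-1], observed[::-1]  # null end first
    for i in range(2 * window, n):
        j = i - window
        current = (obs_a[i] - obs_a[j]) / (exp_a[i] - exp_a[j])
        baseline = (obs_a[j] - obs_a[0]) / (exp_a[j] - exp_a[0])
        if baseline > 0 and current > slope_factor * baseline:
            return float(10 ** -obs_a[i]), table
    return None, table
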