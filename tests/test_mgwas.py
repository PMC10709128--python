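"""Summary-statistics QC, SNP-gene mapping, min-p aggregation, categories."""

import numpy as np
import pandas as pd
import pytest

from srdkit.mgwas import (
    aggregate_min_p,
    classify_significance,
    map_snps_to_genes,
    map_snps_via_eqtl,
    qc_filter,
    qqplot_cutoff,
    read_summary_stats,
    snp_keys,
)
from srdkit.synth import MgwasGenSpec, PathwayGenSpec, generate_pathway, generate_summary_stats


def _records(rows):
    return pd.DataFrame(rows, columns=["CHROM", "POS", "A1", "A2", "METABOLITE", "P", "MAF"])


def _three_met_records(n_variants, maf=0.2, skip=()):
    """n_variants x 3 metabolites; variants in `skip` miss metabolite m3."""
    rows = []
    for i in range(n_variants):
        for m in ("m1", "m2", "m3"):
            if m == "m3" and i in skip:
                continue
            rows.append(("1", 1000 + i, "A", "G", m, 0.5, maf))
    return _records(rows)


class TestQcFilter:
    def test_low_maf_excluded(self):
        df = _three_met_records(2)
        df.loc[df["POS"] == 1000, "MAF"] = 0.005
        out = qc_filter(df)
        assert set(out["POS"]) == {1001}

    def test_maf_boundary_is_strict(self):
        df = _three_met_records(1, maf=0.01)
        assert qc_filter(df).empty

    def test_indels_excluded_by_default_but_flaggable(self):
        df = _three_met_records(1)
        df["A1"] = "AT"
        assert qc_filter(df).empty
        assert len(qc_filter(df, keep_indels=True)) == 3

    def test_counts_match_brute_force(self):
        """100 variants; 10 below MAF, 5 others incomplete: 85 survive."""
        df = _three_met_records(100, skip=set(range(10, 15)))
        df.loc[df["POS"].isin(range(1000, 1010)), "MAF"] = 0.001
        out = qc_filter(df)
        # independent recount: per-variant scan of the long table
        survivors = set()
        for pos, sub in df.groupby("POS"):
            if (sub["MAF"] > 0.01).all() and sub["METABOLITE"].nunique() == 3:
                survivors.add(pos)
        assert len(survivors) == 85
        assert set(out["POS"]) == survivors
        counts = out.attrs["qc_counts"]
        assert counts["excluded_maf"] == 10 * 3
        assert counts["excluded_incomplete"] == 5 * 2

    def test_missing_column_is_schema_error(self):
        with pytest.raises(ValueError, match="MAF"):
            qc_filter(_three_met_records(2).drop(columns="MAF"))


INTERVALS = pd.DataFrame(
    {
        "chrom": ["1", "1", "2"],
        "start": [50_000, 55_000, 10_000],
        "end": [70_000, 80_000, 20_000],
        "name": ["iv1", "iv2", "iv3"],
        "score": [0, 0, 0],
        "strand": ["+", "-", "+"],
        "gene_symbol": ["GA", "GB", "GC"],
        "kegg_gene_id": ["hsa:1", "hsa:2", "hsa:3"],
    }
)


class TestIntervalMapping:
    def test_flank_boundary_half_open(self):
        flank = 10_000
        # 0-based start-flank = 40000 -> 1-based POS 40001 included, 40000 not
        inside = _records([("1", 40_001, "A", "G", "m1", 0.5, 0.2)])
        outside = _records([("1", 40_000, "A", "G", "m1", 0.5, 0.2)])
        last_in = _records([("1", 80_000, "A", "G", "m1", 0.5, 0.2)])  # pos0 = 79999
        beyond = _records([("1", 80_001, "A", "G", "m1", 0.5, 0.2)])  # pos0 = end+flank
        assert set(map_snps_to_genes(inside, INTERVALS, flank)["kegg_gene_id"]) == {"hsa:1"}
        assert map_snps_to_genes(outside, INTERVALS, flank).query("kegg_gene_id == 'hsa:1'").empty
        assert "hsa:1" in set(map_snps_to_genes(last_in, INTERVALS, flank)["kegg_gene_id"])
        # end+flank is half-open: pos0 = 80000 is the first position beyond hsa:1
        assert map_snps_to_genes(beyond, INTERVALS, flank).query("kegg_gene_id == 'hsa:1'").empty

    def test_overlapping_genes_give_two_links(self):
        df = _records([("1", 60_001, "A", "G", "m1", 0.5, 0.2)])
        links = map_snps_to_genes(df, INTERVALS, 0)
        assert sorted(links["kegg_gene_id"]) == ["hsa:1", "hsa:2"]

    def test_enzyme_restriction(self):
        df = _records([("1", 60_001, "A", "G", "m1", 0.5, 0.2)])
        links = map_snps_to_genes(df, INTERVALS, 0, enzyme_genes=frozenset({"hsa:2"}))
        assert sorted(links["kegg_gene_id"]) == ["hsa:2"]

    def test_chromosome_mismatch_is_explicit_error(self):
        df = _records([("chr1", 60_001, "A", "G", "m1", 0.5, 0.2)])
        with pytest.raises(ValueError, match="chromosome naming"):
            map_snps_to_genes(df, INTERVALS, 0)

    def test_wider_flank_is_superset(self, rng):
        rows = [
            ("1", int(rng.integers(1, 200_000)), "A", "G", "m1", 0.5, 0.2) for _ in range(1000)
        ]
        df = _records(rows).drop_duplicates(["POS"])
        narrow = map_snps_to_genes(df, INTERVALS, 10_000)
        wide = map_snps_to_genes(df, INTERVALS, 50_000)
        key_n = set(zip(snp_keys(narrow), narrow["kegg_gene_id"]))
        key_w = set(zip(snp_keys(wide), wide["kegg_gene_id"]))
        assert key_n <= key_w
        # brute-force recount of the wide mapping
        brute = set()
        for row in df.itertuples(index=False):
            for iv in INTERVALS.itertuples(index=False):
                if iv.chrom == row.CHROM and iv.start - 50_000 <= row.POS - 1 < iv.end + 50_000:
                    brute.add((f"{row.CHROM}_{row.POS}_{row.A1}_{row.A2}", iv.kegg_gene_id))
        assert key_w == brute


class TestEqtlMapping:
    def _eqtl(self, fdr):
        return pd.DataFrame(
            {"snp_key": ["1_60001_A_G"], "gene_symbol": ["GC"], "fdr": [fdr]}
        )

    def test_fdr_threshold(self):
        df = _records([("1", 60_001, "A", "G", "m1", 0.5, 0.2)])
        assert map_snps_via_eqtl(df, self._eqtl(0.06), INTERVALS).empty
        links = map_snps_via_eqtl(df, self._eqtl(0.04), INTERVALS)
        assert list(links["kegg_gene_id"]) == ["hsa:3"]
        assert list(links["mapping_source"]) == ["eqtl"]

    def test_unknown_gene_symbol_skipped(self):
        df = _records([("1", 60_001, "A", "G", "m1", 0.5, 0.2)])
        eqtl = self._eqtl(0.01)
        eqtl["gene_symbol"] = "NOSUCH"
        assert map_snps_via_eqtl(df, eqtl, INTERVALS).empty

    def test_dual_source_pair_records_both(self):
        df = _records([("1", 60_001, "A", "G", "m1", 1e-9, 0.2)])
        iv_links = map_snps_to_genes(df, INTERVALS, 0)
        eqtl = pd.DataFrame({"snp_key": ["1_60001_A_G"], "gene_symbol": ["GA"], "fdr": [0.01]})
        eq_links = map_snps_via_eqtl(df, eqtl, INTERVALS)
        pairs = aggregate_min_p(pd.concat([iv_links, eq_links]), df)
        row = pairs[pairs["kegg_gene_id"] == "hsa:1"].iloc[0]
        assert row["mapping_source"] == "eqtl;interval"


class TestAggregate:
    def test_min_p_kept(self):
        df = _records(
            [
                ("1", 60_001, "A", "G", "m1", 1e-5, 0.2),
                ("1", 60_002, "A", "G", "m1", 1e-8, 0.2),
                ("1", 60_003, "A", "G", "m1", 1e-3, 0.2),
            ]
        )
        links = map_snps_to_genes(df, INTERVALS, 0)
        pairs = aggregate_min_p(links, df)
        row = pairs[pairs["kegg_gene_id"] == "hsa:1"].iloc[0]
        assert row["min_p"] == 1e-8
        assert row["best_snp"] == "1_60002_A_G"

    def test_tie_broken_by_position(self):
        df = _records(
            [
                ("1", 60_005, "A", "G", "m1", 1e-8, 0.2),
                ("1", 60_002, "A", "G", "m1", 1e-8, 0.2),
            ]
        )
        links = map_snps_to_genes(df, INTERVALS, 0)
        pairs = aggregate_min_p(links, df)
        assert pairs[pairs["kegg_gene_id"] == "hsa:1"].iloc[0]["best_snp"] == "1_60002_A_G"

    def test_matches_brute_force_groupby(self, rng):
        gp = generate_pathway(PathwayGenSpec(seed=4))
        ds = generate_summary_stats(gp, MgwasGenSpec(seed=4))
        links = map_snps_to_genes(ds.summary_stats, ds.intervals, 10_000)
        pairs = aggregate_min_p(links, ds.summary_stats)
        merged = links.merge(ds.summary_stats, on=["CHROM", "POS", "A1", "A2"])
        brute = merged.groupby(["kegg_gene_id", "METABOLITE"])["P"].min()
        for row in pairs.itertuples(index=False):
            assert row.min_p == brute[(row.kegg_gene_id, row.metabolite_key)]
        assert len(pairs) == len(brute)


class TestClassification:
    def _pairs(self, pvals):
        return pd.DataFrame({"kegg_gene_id": "hsa:1", "metabolite_key": "m", "min_p": pvals})

    def test_bonferroni_derivation(self):
        out = classify_significance(self._pairs([1e-12]), n_metabolites=128)
        assert out.attrs["thresholds"]["genomewide_p"] == 7.8125e-10

    def test_bands_and_boundaries(self):
        gw = 7.8125e-10
        pvals = [1e-12, gw, 5e-8, 1e-7, 1e-6, 3.16e-5, 0.5]
        out = classify_significance(self._pairs(pvals), genomewide_p=gw)
        assert list(out["category"]) == [
            "R", "S_plus", "S_plus", "S_minus", "S_minus", "NS", "NS",
        ]

    def test_partition(self, rng):
        pvals = 10.0 ** -rng.uniform(0, 12, size=1000)
        out = classify_significance(self._pairs(pvals), n_metabolites=128)
        counts = out["category"].value_counts()
        assert counts.sum() == 1000
        # brute-force binning
        gw, sg, pl = 7.8125e-10, 1e-7, 3.16e-5
        brute = {
            "R": int((pvals < gw).sum()),
            "S_plus": int(((pvals >= gw) & (pvals < sg)).sum()),
            "S_minus": int(((pvals >= sg) & (pvals < pl)).sum()),
            "NS": int((pvals >= pl).sum()),
        }
        assert counts.to_dict() == brute

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="genome-wide < suggestive"):
            classify_significance(self._pairs([0.5]), genomewide_p=1e-3, suggestive_p=1e-7)


class TestQqplotCutoff:
    def test_too_few_values(self):
        with pytest.raises(ValueError):
            qqplot_cutoff([0.5] * 99)

    def test_uniform_has_no_departure(self, rng):
        p = rng.uniform(size=2000)
        threshold, table = qqplot_cutoff(p)
        assert threshold is None
        assert len(table) == 2000
        assert table["observed"].is_monotonic_decreasing

    def test_mixture_detected_between_populations(self, rng):
        """5% of p values planted at 1e-8 deflect the QQ curve.

        The detected threshold sits in the deflected tail: well below the
        bulk of the uniform population (its 5th percentile) and at or above
        the planted population.  Detection slightly before the planted jump
        is expected — displacing 5% of the ranks stretches the uniform
        quantiles upward already.
        """
        p = np.concatenate([rng.uniform(size=1900), np.full(100, 1e-8)])
        threshold, _ = qqplot_cutoff(p)
        assert threshold is not None
        assert 1e-8 <= threshold < 0.05

    def test_constructed_kink(self):
        # quantiles that follow the null diagonal up to -log10(p) = 2, then
        # climb five times steeper: the detected cutoff is past the kink
        n = 1000
        expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        obs = np.where(expected <= 2.0, expected, 2.0 + 5.0 * (expected - 2.0))
        threshold, _ = qqplot_cutoff(10.0 ** -obs)
        assert threshold is not None
        assert 10.0 ** -8.6 <= threshold <= 0.01


def test_read_summary_stats_schema(tmp_path):
    f = tmp_path / "ss.tsv"
    _three_met_records(3).to_csv(f, sep="\t", index=False)
    df = read_summary_stats(f)
    assert list(df.columns[:7]) == ["CHROM", "POS", "A1", "A2", "METABOLITE", "P", "MAF"]
    f2 = tmp_path / "bad.tsv"
    _three_met_records(3).drop(columns="P").to_csv(f2, sep="\t", index=False)
    with pytest.raises(ValueError, match="P"):
        read_summary_stats(f2)
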