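"""Strand merging, censoring, weighted levels and site categorization."""

import math

import numpy as np
import pandas as pd
import pytest

from epiril import cg
from epiril.synthetic import simulate_count_table


def _stranded(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n_meth",
                                       "n_unmeth", "context"])


class TestMergeStrands:
    def test_identical_strands_merge(self):
        table = _stranded([("chr1", 10, "+", 5, 0, "CG"),
                           ("chr1", 11, "-", 5, 0, "CG")])
        out = cg.merge_strand_table(table)
        row = out.iloc[0]
        assert row["status"] == cg.STATUS_MERGED
        assert row["level"] == 1.0
        assert row["p_adj"] == pytest.approx(1.0)
        assert (row["n_meth"], row["n_unmeth"]) == (10, 0)

    def test_opposite_strands_censored(self):
        table = _stranded([("chr1", 10, "+", 10, 0, "CG"),
                           ("chr1", 11, "-", 0, 10, "CG")])
        out = cg.merge_strand_table(table)
        row = out.iloc[0]
        # two-sided Fisher p for the fully discordant table
        assert row["p_adj"] == pytest.approx(2 / math.comb(20, 10))
        assert row["status"] == cg.STATUS_INCONSISTENT
        assert np.isnan(row["level"])

    def test_nonsignificant_difference_pools(self):
        table = _stranded([("chr1", 10, "+", 3, 1, "CG"),
                           ("chr1", 11, "-", 0, 4, "CG")])
        out = cg.merge_strand_table(table)
        row = out.iloc[0]
        assert row["status"] == cg.STATUS_MERGED
        assert row["level"] == pytest.approx(3 / 8)

    def test_single_strand_flagged_and_excluded(self):
        table = _stranded([("chr1", 10, "+", 4, 0, "CG"),
                           ("chr2", 20, "+", 2, 2, "CG"),
                           ("chr2", 21, "-", 2, 2, "CG")])
        out = cg.merge_strand_table(table)
        assert out.set_index("chrom").loc["chr1", "status"] \
            == cg.STATUS_SINGLE
        assert len(cg.usable(out)) == 1

    def test_read_conservation(self, merged_rep1, ril):
        total_in = ril.rep1.loc[ril.rep1["context"] == "CG",
                                ["n_meth", "n_unmeth"]].to_numpy().sum()
        total_out = merged_rep1[["n_meth", "n_unmeth"]].to_numpy().sum()
        assert total_in == total_out

    def test_null_inconsistency_rate_below_two_per_mille(self):
        """Same true level on both strands: <0.2% censored inconsistent."""
        rng = np.random.default_rng(0)
        n = 100_000
        levels = rng.choice([0.05, 0.5, 0.95], size=n)
        depth_f = rng.poisson(20, n)
        depth_r = rng.poisson(20, n)
        fw = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) * 10,
                           "strand": "+",
                           "n_meth": rng.binomial(depth_f, levels),
                           "context": "CG"})
        fw["n_unmeth"] = depth_f - fw["n_meth"]
        rv = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) * 10 + 1,
                           "strand": "-",
                           "n_meth": rng.binomial(depth_r, levels),
                           "context": "CG"})
        rv["n_unmeth"] = depth_r - rv["n_meth"]
        out = cg.merge_strand_table(pd.concat([fw, rv], ignore_index=True))
        frac = (out["status"] == cg.STATUS_INCONSISTENT).mean()
        assert frac <= 0.002


class TestSnpCensoring:
    def test_snp_at_either_position_censors_merged_cg(self):
        merged = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 50],
                               "n_meth": [5, 5], "n_unmeth": [0, 0],
                               "level": [1.0, 1.0],
                               "status": [cg.STATUS_MERGED] * 2})
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [11],
                             "allele1": ["A"], "allele2": ["G"]})
        out = cg.censor_snp_overlaps(merged, snps)
        assert out.iloc[0]["status"] == cg.STATUS_SNP
        assert out.iloc[1]["status"] == cg.STATUS_MERGED

    def test_empty_snp_table_is_identity(self):
        merged = pd.DataFrame({"chrom": ["chr1"], "pos": [10],
                               "n_meth": [5], "n_unmeth": [0],
                               "level": [1.0], "status": [cg.STATUS_MERGED]})
        out = cg.censor_snp_overlaps(merged, pd.DataFrame(
            columns=["chrom", "pos", "allele1", "allele2"]))
        pd.testing.assert_frame_equal(out, merged)

    def test_stranded_record_censors_only_its_own_position(self):
        table = _stranded([("chr1", 30, "+", 1, 1, "CHH"),
                           ("chr1", 31, "+", 1, 1, "CHH")])
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [30],
                             "allele1": ["A"], "allele2": ["G"]})
        out = cg.censor_snp_overlaps(table, snps)
        assert out["censored_snp"].tolist() == [True, False]


class TestWeightedMethylation:
    def test_arithmetic(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [5, 15],
                              "n_meth": [3, 0], "n_unmeth": [1, 4]})
        assert cg.weighted_methylation(sites, ("chr1", 0, 100),
                                       min_cov=4, min_sites=2) \
            == pytest.approx(3 / 8)

    def test_min_sites_censoring(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [5],
                              "n_meth": [3], "n_unmeth": [1]})
        assert np.isnan(cg.weighted_methylation(sites, ("chr1", 0, 100),
                                                min_cov=4, min_sites=5))

    def test_fully_methylated_boundary(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": range(5),
                              "n_meth": [9] * 5, "n_unmeth": [0] * 5})
        assert cg.weighted_methylation(sites) == 1.0


class TestCategorization:
    def test_published_style_corner_fractions(self):
        # fractions recomputed from corner counts via level placeholders
        counts = {"both_low": 673_701, "p2_only": 10_500,
                  "p1_only": 79_667, "both_high": 51_575}
        total = 867_234
        inter = total - sum(counts.values())
        p1 = np.concatenate([
            np.full(counts["both_low"], 0.1), np.full(counts["p2_only"], 0.1),
            np.full(counts["p1_only"], 0.9), np.full(counts["both_high"], 0.9),
            np.full(inter, 0.5)])
        p2 = np.concatenate([
            np.full(counts["both_low"], 0.1), np.full(counts["p2_only"], 0.9),
            np.full(counts["p1_only"], 0.1), np.full(counts["both_high"], 0.9),
            np.full(inter, 0.5)])
        _, fr = cg.categorize_sites(p1, p2)
        assert round(100 * fr["both_low"], 1) == 77.7
        assert round(100 * fr["p1_only"], 1) == 9.2
        assert round(100 * fr["p2_only"], 1) == 1.2
        assert round(100 * fr["both_high"], 1) == 5.9

    def test_intermediate_and_partition(self):
        cats, fr = cg.categorize_sites([0.5, 0.1, 0.9], [0.5, 0.95, 0.05])
        assert cats.tolist() == ["intermediate", "p2_only", "p1_only"]
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_gene_category_fractions(self):
        sites = pd.DataFrame({
            "chrom": "chr1",
            "pos": list(range(0, 100, 10)) + list(range(200, 290, 10)),
            "category": ["both_low"] * 10
            + ["p1_only"] * 5 + ["both_high"] * 4,
        })
        genes = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [0, 200], "end": [150, 300],
                              "name": ["gA", "gB"], "score": 0,
                              "strand": "+"})
        out = cg.gene_category_fractions(sites, genes, min_classified=10)
        assert out.loc["gA"].tolist() == [1.0, 0.0, 0.0, 0.0]
        assert "gB" not in out.index  # only 9 classified CGs

    def test_gene_split_example(self):
        sites = pd.DataFrame({
            "chrom": "chr1", "pos": range(0, 100, 10),
            "category": ["p1_only"] * 5 + ["both_high"] * 5})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                              "name": ["g"], "score": 0, "strand": "+"})
        out = cg.gene_category_fractions(sites, genes)
        assert out.loc["g"].tolist() == [0.0, 0.5, 0.0, 0.5]


class TestReplicateCorrelation:
    def test_exact_cases(self):
        a = pd.Series([0.1, 0.5, 0.9], index=[1, 2, 3])
        assert cg.replicate_correlation(a, a) == pytest.approx(1.0)
        assert cg.replicate_correlation(a, 1 - a) == pytest.approx(-1.0)

    def test_insufficient_shared_sites(self):
        a = pd.Series([0.1, 0.5], index=[1, 2])
        with pytest.raises(cg.InsufficientDataError):
            cg.replicate_correlation(a, a)

    def test_against_covariance_formula_on_synthetic_replicates(self):
        """Pearson r over 10^4 depth-20 sites vs direct covariance oracle."""
        rng = np.random.default_rng(1)
        levels = rng.choice([0.05, 0.5, 0.9], size=10_000)
        t1 = simulate_count_table(levels, 20.0, np.random.default_rng(2))
        t2 = simulate_count_table(levels, 20.0, np.random.default_rng(3))
        a = pd.Series(t1["level"].to_numpy(), index=t1["pos"])
        b = pd.Series(t2["level"].to_numpy(), index=t2["pos"])
        r = cg.replicate_correlation(a, b)
        x, y = a.dropna().align(b.dropna(), join="inner")
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std(ddof=0) * y.std(ddof=0))
        assert r == pytest.approx(oracle)
        assert r > 0.9
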