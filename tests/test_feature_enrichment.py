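"""Binomial feature enrichment: exact-p oracle, BH, strata, families."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from modscape.feature_enrichment import (
    bh_adjust,
    binomial_feature_test,
    derive_promoters,
    eligible_base_count,
    expression_strata,
    feature_class_table,
    merge_intervals,
    per_family_fold,
)
from modscape.io_core import (
    ConfigError,
    ExpressionTable,
    FeatureSet,
    GenomeSeq,
    Interval,
    ModCall,
    ModTable,
)
from modscape.synthetic_data import (
    MotifSpec,
    gen_features,
    gen_genome,
    plant_motif_mods,
)


def exact_two_sided_p(observed, n, p):
    """Independent oracle: minimum-likelihood two-sided binomial p."""
    pmf = binom.pmf(np.arange(n + 1), n, p)
    return float(pmf[pmf <= pmf[observed] * (1 + 1e-12)].sum())


class TestEligibleCounts:
    def test_both_strand_enumeration(self):
        # "AACC": + strand has A at 0,1; - strand (GGTT) has A at 3,2
        g = GenomeSeq([("c1", "AACC")])
        fs = FeatureSet([Interval("c1", 0, 2, "+", "region", "r1")])
        eligible_in, eligible_total = eligible_base_count(g, fs, "A")
        assert eligible_in == 2  # the two forward A's; no T's in [0,2)
        assert eligible_total == 2  # genome-wide: two A's, no T's

    def test_whole_genome_feature(self, small_genome):
        n = small_genome.lengths["contig_1"]
        fs = FeatureSet([Interval("contig_1", 0, n, ".", "region", "all"),
                         Interval("contig_2", 0, n, ".", "region", "all2")])
        ein, etot = eligible_base_count(small_genome, fs, "A")
        assert ein == etot

    def test_overlap_counted_once(self, small_genome):
        one = FeatureSet([Interval("contig_1", 100, 300, ".", "r", "a")])
        two = FeatureSet([Interval("contig_1", 100, 300, ".", "r", "a"),
                          Interval("contig_1", 150, 300, ".", "r", "b")])
        assert eligible_base_count(small_genome, one, "A") == \
            eligible_base_count(small_genome, two, "A")

    def test_merge_intervals(self):
        fs = FeatureSet([Interval("c1", 0, 10, ".", "r", "a"),
                         Interval("c1", 5, 20, ".", "r", "b"),
                         Interval("c1", 30, 40, ".", "r", "c")])
        m = merge_intervals(fs)
        assert m["c1"].tolist() == [[0, 20], [30, 40]]


class TestBinomialTest:
    def test_p_matches_pmf_summation_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 300))
            p = float(rng.uniform(0.02, 0.9))
            obs = int(rng.integers(0, n + 1))
            from scipy.stats import binomtest
            ours = binomtest(obs, n, p, alternative="two-sided").pvalue
            assert ours == pytest.approx(exact_two_sided_p(obs, n, p),
                                         abs=1e-10)

    def test_fold_and_p_on_constructed_instance(self):
        g = GenomeSeq([("c1", "A" * 10_000)])
        fs = FeatureSet([Interval("c1", 0, 1000, ".", "gene", "g1")])
        calls = [ModCall("c1", i, "+", "A", "6mA") for i in range(10)] + \
            [ModCall("c1", 1000 + 200 * i, "+", "A", "6mA") for i in range(40)]
        r = binomial_feature_test(ModTable(calls), g, fs, "gene", "6mA")
        assert r.observed == 10 and r.n_total == 50
        assert r.fold == pytest.approx(10 / (50 * 0.1))
        assert r.p == pytest.approx(exact_two_sided_p(10, 50, 0.1), abs=1e-10)

    def test_whole_genome_feature_is_null(self, small_genome, gagg_mods):
        mods, _ = gagg_mods
        n1 = small_genome.lengths["contig_1"]
        n2 = small_genome.lengths["contig_2"]
        fs = FeatureSet([Interval("contig_1", 0, n1, ".", "all", "a1"),
                         Interval("contig_2", 0, n2, ".", "all", "a2")])
        r = binomial_feature_test(mods, small_genome, fs, "all", "6mA")
        assert r.fold == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_no_calls_returns_none(self, small_genome):
        fs = FeatureSet([Interval("contig_1", 0, 100, ".", "gene", "g")])
        assert binomial_feature_test(ModTable([]), small_genome, fs,
                                     "gene", "6mA") is None

    def test_partition_additivity(self, small_genome, gagg_mods):
        """Disjoint feature classes partitioning the genome capture every
        call exactly once."""
        mods, _ = gagg_mods
        fs = []
        for contig, length in small_genome.lengths.items():
            half = length // 2
            fs.append(Interval(contig, 0, half, ".", "left", f"L_{contig}"))
            fs.append(Interval(contig, half, length, ".", "right",
                               f"R_{contig}"))
        table = feature_class_table(mods, small_genome, FeatureSet(fs), "6mA")
        assert table["observed"].sum() == len(mods.filter("6mA"))


class TestBH:
    def test_hand_computed(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_adjust([0.5, 1.5])


class TestPerFamilyFold:
    def test_planted_hot_family_recovered(self):
        g = gen_genome(400_000, 0.38, 1, seed=91)
        feats = gen_features(g, seed=9)
        repeats = feats.of_type("repeat")
        hot = FeatureSet([iv for iv in repeats if iv.id.startswith("fam1")])
        # background everywhere + 10x concentration inside fam1
        mods_bg, _ = plant_motif_mods(g, [MotifSpec("A", 0, "6mA", 0.002)],
                                      0.0, seed=1)
        rng = np.random.default_rng(2)
        extra = []
        for iv in hot:
            seq = g.seq(iv.contig)[iv.start:iv.end]
            for i, b in enumerate(seq):
                if b == "A" and rng.random() < 0.018:
                    extra.append(ModCall(iv.contig, iv.start + i, "+", "A",
                                         "6mA"))
        merged = {(c.contig, c.pos, c.strand): c
                  for c in list(mods_bg) + extra}
        mods = ModTable(merged.values())
        df, excluded = per_family_fold(mods, g, repeats, "6mA")
        fam1 = df[df["family"] == "fam1"].iloc[0]
        others = df[df["family"] != "fam1"]
        assert fam1["fold"] > 3
        assert fam1["q"] < 0.05
        assert (others["fold"] < fam1["fold"]).all()

    def test_min_eligible_filter(self, small_genome):
        repeats = FeatureSet([Interval("contig_1", 0, 30, ".", "repeat",
                                       "tiny:1"),
                              Interval("contig_1", 100, 2000, ".", "repeat",
                                       "big:1")])
        mods = ModTable([ModCall("contig_1", i, "+", "A", "6mA")
                         for i, b in enumerate(small_genome.seq("contig_1")[:500])
                         if b == "A"][:20])
        df, excluded = per_family_fold(mods, small_genome, repeats, "6mA",
                                       min_eligible=100)
        assert "tiny" in excluded
        assert set(df["family"]) == {"big"}

    def test_zero_observed_family(self, small_genome):
        repeats = FeatureSet([Interval("contig_2", 0, 5000, ".", "repeat",
                                       "cold:1")])
        mods = ModTable([ModCall("contig_1", 10, "+", "A", "6mA"),
                         ModCall("contig_1", 500, "+", "A", "6mA")])
        df, _ = per_family_fold(mods, small_genome, repeats, "6mA")
        assert df.iloc[0]["fold"] == 0.0


class TestStrataAndPromoters:
    def test_strata_boundaries(self):
        t = ExpressionTable({"g0": (0.0, 1.0, "c1"), "g5": (5.0, 1.0, "c1"),
                             "g10": (10.0, 1.0, "c1"),
                             "g01": (0.1, 1.0, "c1")})
        s = expression_strata(t, thresholds=(0.1, 10.0))
        assert s == {"g0": "unexpressed", "g01": "unexpressed",
                     "g5": "low", "g10": "high"}

    def test_bad_thresholds(self):
        with pytest.raises(ConfigError):
            expression_strata(ExpressionTable({}), thresholds=(10, 0.1))

    def test_promoters_strand_aware_and_clipped(self):
        g = GenomeSeq([("c1", "A" * 2000)])
        fs = FeatureSet([Interval("c1", 300, 900, "+", "gene", "gp"),
                         Interval("c1", 1000, 1600, "-", "gene", "gm"),
                         Interval("c1", 100, 200, "+", "gene", "gedge")])
        proms = {iv.id: iv for iv in derive_promoters(fs, g, upstream=500)}
        assert (proms["gp_prom"].start, proms["gp_prom"].end) == (0, 300)
        assert (proms["gm_prom"].start, proms["gm_prom"].end) == (1600, 2000)
        assert (proms["gedge_prom"].start, proms["gedge_prom"].end) == (0, 100)
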