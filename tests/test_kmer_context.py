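"""K-mer context statistics: counting oracles, residual formula, PWM."""

import itertools
import math

import numpy as np
import pytest

from modscape.io_core import ConfigError, GenomeSeq, ModCall, ModTable, revcomp
from modscape.kmer_context import (
    KmerCountTable,
    UndefinedRatioError,
    background_kmer_counts,
    build_pwm,
    genome_trimer_depletion,
    methylation_frequency_summary,
    modification_rate_table,
    modified_kmer_counts,
    rate_ratio,
    select_enriched_kmers,
    standardized_residuals,
)
from modscape.synthetic_data import MotifSpec, gen_genome, plant_motif_mods


def brute_force_background(genome, k, target_base, offset):
    """Independent oracle: enumerate windows on both strands as strings."""
    counts = {}
    for name, seq in genome.items():
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                w = s[i: i + k]
                if "N" in w or w[offset] != target_base:
                    continue
                counts[w] = counts.get(w, 0) + 1
    return counts


class TestBackgroundCounts:
    def test_gagg_trimer_enumeration(self):
        g = GenomeSeq([("c1", "GAGG")])
        t = background_kmer_counts(g, 3, "A", 1)
        # + strand: GAG (A at offset 1); - strand CCTC has no A at offset 1
        assert t.counts == {"GAG": 1}
        assert t.total == 1

    def test_all_a_k1_saturation(self):
        g = GenomeSeq([("c1", "A" * 50)])
        # every + strand position is an eligible A; the minus strand of a
        # poly-A contig is poly-T and contributes none
        t = background_kmer_counts(g, 1, "A", 0)
        assert t.total == 50
        # a poly-AT alternation has 50 eligible A on each strand
        g2 = GenomeSeq([("c1", "AT" * 50)])
        assert background_kmer_counts(g2, 1, "A", 0).total == 100

    def test_contig_shorter_than_k_is_empty(self):
        g = GenomeSeq([("c1", "AC")])
        t = background_kmer_counts(g, 3, "A", 1)
        assert t.counts == {}

    @pytest.mark.parametrize("k,offset", [(1, 0), (2, 1), (3, 1), (4, 2)])
    def test_matches_string_enumeration_oracle(self, k, offset):
        g = gen_genome(3000, gc=0.45, n_contigs=2, seed=21)
        t = background_kmer_counts(g, k, "A", offset)
        assert t.counts == brute_force_background(g, k, "A", offset)

    def test_n_windows_excluded(self):
        g = GenomeSeq([("c1", "GANGAG")])
        t = background_kmer_counts(g, 3, "A", 1)
        oracle = brute_force_background(g, 3, "A", 1)
        assert t.counts == oracle


class TestModifiedCounts:
    def test_plus_strand_context(self):
        g = GenomeSeq([("c1", "TGAGGT")])
        mods = ModTable([ModCall("c1", 2, "+", "A", "6mA")])
        t = modified_kmer_counts(mods, g, 3, 1, "6mA")
        assert t.counts == {"GAG": 1}

    def test_minus_strand_context_is_reverse_complement(self):
        # CCTC on the forward strand is GAGG on the minus strand;
        # the minus-strand A sits opposite forward position 2 (the middle T)
        g = GenomeSeq([("c1", "TCCTCT")])
        mods = ModTable([ModCall("c1", 3, "-", "A", "6mA")])
        t = modified_kmer_counts(mods, g, 3, 1, "6mA")
        assert t.counts == {"GAG": 1}

    def test_edge_call_dropped(self):
        g = GenomeSeq([("c1", "AGGT")])
        mods = ModTable([ModCall("c1", 0, "+", "A", "6mA")])
        t = modified_kmer_counts(mods, g, 3, 1, "6mA")
        assert t.counts == {} and t.dropped == 1

    def test_strand_symmetry(self, small_genome, gagg_mods):
        """Reverse-complementing the genome and flipping strands leaves
        every context count unchanged."""
        mods, _ = gagg_mods
        fwd = modified_kmer_counts(mods, small_genome, 3, 1, "6mA")
        flipped_genome = GenomeSeq(
            [(n, revcomp(s)) for n, s in small_genome.items()])
        flipped_calls = [
            ModCall(c.contig, small_genome.lengths[c.contig] - 1 - c.pos,
                    "-" if c.strand == "+" else "+", c.base, c.mod_class,
                    c.coverage, c.score, c.frac) for c in mods]
        rev = modified_kmer_counts(ModTable(flipped_calls), flipped_genome,
                                   3, 1, "6mA")
        assert fwd.counts == rev.counts


class TestStandardizedResiduals:
    def test_hand_computed_example(self):
        bg = KmerCountTable(3, "A", 1, {"CAG": 60, "GAG": 40})
        obs = KmerCountTable(3, "A", 1, {"CAG": 2, "GAG": 8})
        r = standardized_residuals(obs, bg)
        assert r.expected["GAG"] == pytest.approx(4.0)
        assert r.residual["GAG"] == pytest.approx(
            (8 - 4) / math.sqrt(4 * 0.6), abs=1e-9)
        assert r.residual["CAG"] == pytest.approx(-2.581988897, abs=1e-6)

    def test_null_case_zero_residuals(self):
        bg = KmerCountTable(1, "A", 0, {"A": 1000})
        obs = KmerCountTable(1, "A", 0, {"A": 10})
        r = standardized_residuals(obs, bg)
        assert r.residual["A"] == pytest.approx(0.0)

    def test_expected_sums_to_n_mod(self, small_genome, gagg_mods):
        mods, _ = gagg_mods
        bg = background_kmer_counts(small_genome, 3, "A", 1)
        obs = modified_kmer_counts(mods, small_genome, 3, 1, "6mA")
        r = standardized_residuals(obs, bg)
        assert sum(r.expected.values()) == pytest.approx(
            r.n_mod, rel=1e-9)
        assert sum(r.obs.values()) + obs.dropped == len(mods.filter("6mA"))

    def test_brute_force_equivalence_random_instances(self, rng):
        """Residuals match a direct formula evaluation to 1e-9."""
        for _ in range(25):
            n_cat = int(rng.integers(2, 65))
            kmers = [f"K{i}" for i in range(n_cat)]
            bg = {w: int(rng.integers(1, 1000)) for w in kmers}
            obs = {w: int(rng.integers(0, 50)) for w in kmers}
            bt = KmerCountTable(1, "A", 0, bg)
            ot = KmerCountTable(1, "A", 0, obs)
            bt_total, n = sum(bg.values()), sum(obs.values())
            res = standardized_residuals(ot, bt)
            pearson = standardized_residuals(ot, bt, variant="pearson")
            chi2 = 0.0
            for w in kmers:
                p = bg[w] / bt_total
                e = n * p
                expect = (obs[w] - e) / math.sqrt(e * (1 - p))
                assert res.residual[w] == pytest.approx(expect, abs=1e-9)
                chi2 += (obs[w] - e) ** 2 / e
            assert res.chi_square == pytest.approx(chi2, rel=1e-9)
            assert res.chi_square == pytest.approx(
                sum(v ** 2 for v in pearson.residual.values()), rel=1e-9)

    def test_zero_expected_sentinels(self):
        bg = KmerCountTable(1, "A", 0, {"A": 10})
        obs = KmerCountTable(1, "A", 0, {"A": 1, "C": 2})
        r = standardized_residuals(obs, bg)
        assert r.residual["C"] == math.inf
        bg2 = KmerCountTable(1, "A", 0, {"A": 10, "C": 0})
        obs2 = KmerCountTable(1, "A", 0, {"A": 1})
        r2 = standardized_residuals(obs2, bg2)
        assert r2.residual["C"] is None

    def test_mismatched_tables_rejected(self):
        bg = KmerCountTable(3, "A", 1, {"GAG": 10})
        obs = KmerCountTable(3, "A", 2, {"GAG": 10})
        with pytest.raises(ConfigError):
            standardized_residuals(obs, bg)


class TestRateRatio:
    def test_arithmetic_oracle(self):
        # 1000 eligible A (both strands), 50 modified; 100 GAG, 20 modified
        # is exercised through a constructed miniature equivalent
        g = GenomeSeq([("c1", "GAG" + "T" * 7)])  # 1 GAG; A total both strands
        mods = ModTable([ModCall("c1", 1, "+", "A", "6mA")])
        rho = rate_ratio(mods, g, "GAG", 1, "6mA")
        # both strands: A eligible = #A + #T = 1 + 7; GAG occurs once
        # rho = (1/1) / (1/8) = 8
        assert rho == pytest.approx(8.0)

    def test_null_ratio_is_one(self):
        g = GenomeSeq([("c1", "A" * 20)])
        mods = ModTable([ModCall("c1", i, "+", "A", "6mA")
                         for i in range(2, 18)])
        # AAA occurrences and A occurrences are modified at identical rates
        # only in expectation; use saturating calls on every eligible window
        rho = rate_ratio(ModTable([ModCall("c1", i, "+", "A", "6mA")
                                   for i in range(20)]), g, "A", 0, "6mA")
        assert rho == pytest.approx(1.0, rel=0.25)

    def test_absent_kmer_raises(self):
        g = GenomeSeq([("c1", "GCGCGCGC")])  # no AAA on either strand
        with pytest.raises(UndefinedRatioError):
            rate_ratio(ModTable([]), g, "AAA", 1, "6mA")

    def test_recovery_near_planted_ratio(self):
        g = gen_genome(400_000, 0.38, 1, seed=31)
        from modscape.synthetic_data import background_rate_for_rate_ratio
        b = background_rate_for_rate_ratio(g, "GAG", 1, 0.3, 7.5)
        mods, _ = plant_motif_mods(g, [MotifSpec("GAG", 1, "6mA", 0.3)], b,
                                   seed=2)
        rho = rate_ratio(mods, g, "GAG", 1, "6mA")
        assert rho == pytest.approx(7.5, rel=0.10)


class TestSelection:
    def test_threshold(self):
        res = standardized_residuals(
            KmerCountTable(3, "A", 1, {"CAG": 2, "GAG": 8}),
            KmerCountTable(3, "A", 1, {"CAG": 60, "GAG": 40}))
        assert select_enriched_kmers(res, "residual_threshold", 2) == ["GAG"]

    def test_top_n_and_lexicographic_tie(self):
        res = standardized_residuals(
            KmerCountTable(3, "A", 1, {"AAG": 5, "GAG": 5, "CAG": 0}),
            KmerCountTable(3, "A", 1, {"AAG": 10, "GAG": 10, "CAG": 10}))
        assert res.residual["AAG"] == res.residual["GAG"]
        assert select_enriched_kmers(res, "top_n", 1) == ["AAG"]
        assert len(select_enriched_kmers(res, "top_n", 2)) == 2


class TestPWM:
    def test_column_counting(self):
        pwm = build_pwm(["GAGG", "GAGG", "GAGA"])
        assert pwm.probs[3, 2] == pytest.approx(2 / 3)  # G at column 4
        assert pwm.probs[3, 0] == pytest.approx(1 / 3)  # A at column 4
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_single_kmer_full_information(self):
        pwm = build_pwm(["GAGG"])
        assert np.allclose(pwm.information, 2.0)
        assert pwm.consensus() == "GAGG"

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ConfigError):
            build_pwm(["GAG", "GAGG"])

    def test_recovery_consensus_contains_planted_motif(self):
        g = gen_genome(500_000, 0.38, 1, seed=41)
        mods, _ = plant_motif_mods(g, [MotifSpec("GAGG", 1, "6mA", 0.3)],
                                   1e-4, seed=4)
        bg = background_kmer_counts(g, 7, "A", 2)
        obs = modified_kmer_counts(mods, g, 7, 2, "6mA")
        res = standardized_residuals(obs, bg)
        top = select_enriched_kmers(res, "top_n", 500)
        pwm = build_pwm(top, weights=[res.obs[w] for w in top])
        # modified A at 7-mer position 3 (offset 2) -> GAGG spans offsets 1-4
        assert pwm.consensus()[1:5] == "GAGG"


class TestComposition:
    def test_uniform_genome_ratios_near_one(self):
        g = gen_genome(1_000_000, gc=0.5, seed=51)
        for trimer in ("GCG", "GTG", "AAA"):
            _o, _e, ratio = genome_trimer_depletion(g, trimer)
            assert ratio == pytest.approx(1.0, abs=0.05)

    def test_homopolymer_ratio_exact(self):
        g = GenomeSeq([("c1", "A" * 100)])
        obs, exp, ratio = genome_trimer_depletion(g, "AAA")
        # both strands are A-only and T-only; AAA freq = 0.5, exp = 0.5**3
        assert obs == pytest.approx(0.5)
        assert ratio == pytest.approx(obs / exp)

    def test_engineered_depletion(self):
        g = gen_genome(200_000, 0.38, 1, seed=61)
        seq = g.seq("contig_1")
        while "GCG" in seq or "CGC" in seq:  # CGC is GCG on the minus strand
            seq = seq.replace("GCG", "GTG").replace("CGC", "CTC")
        _o, _e, ratio = genome_trimer_depletion(GenomeSeq([("c1", seq)]),
                                                "GCG")
        assert ratio == pytest.approx(0.0, abs=1e-12)


class TestFrequencySummary:
    def test_counting_and_boundaries(self):
        calls = [ModCall("c1", i, "+", "A", "6mA", frac=f)
                 for i, f in enumerate([0.9, 0.6, 0.3])]
        s = methylation_frequency_summary(ModTable(calls), "6mA",
                                          thresholds=(0.0, 0.5))
        assert s.exceeding[0.5] == pytest.approx(2 / 3)
        assert s.exceeding[0.0] == pytest.approx(1.0)
        assert s.hist_counts.sum() == 3

    def test_missing_frac_excluded(self):
        calls = [ModCall("c1", 1, "+", "A", "6mA", frac=0.9),
                 ModCall("c1", 5, "+", "A", "6mA", frac=None)]
        s = methylation_frequency_summary(ModTable(calls), "6mA", (0.5,))
        assert s.n == 1

    def test_no_frac_returns_none(self):
        calls = [ModCall("c1", 1, "+", "A", "6mA")]
        assert methylation_frequency_summary(ModTable(calls), "6mA") is None

    def test_beta_tail_matches_cdf(self):
        from scipy.stats import beta as beta_dist
        g = gen_genome(2_000_000, 0.38, 1, seed=71)
        mods, _ = plant_motif_mods(g, [MotifSpec("GAG", 1, "6mA", 0.15)],
                                   0.0, seed=7)
        s = methylation_frequency_summary(mods, "6mA", thresholds=(0.8,))
        assert s.n >= 5000
        expect = beta_dist(8, 2).sf(0.8)
        tol = 3 * math.sqrt(expect * (1 - expect) / s.n)
        assert abs(s.exceeding[0.8] - expect) < tol


class TestRateTable:
    def test_saturating_rate(self):
        g = GenomeSeq([("c1", "A" * 30)])
        mods = ModTable([ModCall("c1", i, "+", "A", "6mA") for i in range(30)])
        df = modification_rate_table(mods, g, contexts=[("A", 0)])
        assert df.iloc[0]["rate"] == pytest.approx(1.0)

    def test_no_calls_zero_rates(self, small_genome):
        df = modification_rate_table(ModTable([]), small_genome,
                                     contexts=[("A", 0)],
                                     mod_classes=["6mA"])
        assert (df["rate"] == 0).all()

    def test_binomial_recovery_of_planted_rate(self):
        g = gen_genome(300_000, 0.38, 1, seed=81)
        mods, _ = plant_motif_mods(g, [MotifSpec("A", 0, "6mA", 0.01)],
                                   0.0, seed=8)
        df = modification_rate_table(mods, g, contexts=[("A", 0)])
        n = df.iloc[0]["n_occurrences"]
        assert n >= 1e5
        tol = 3 * math.sqrt(0.01 * 0.99 / n)
        assert df.iloc[0]["rate"] == pytest.approx(0.01, abs=tol)
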