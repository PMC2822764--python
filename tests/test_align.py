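import math
import random

import pytest
from hypothesis import given, strategies as st

from tandemscan.align import (AlignParams, Hsp, aggregate_tb, bit_score,
                              evalue, search_window, search_window_tblastn)

P = AlignParams()


def mk_hsp(q0, q1, bits, strand="+"):
    return Hsp(q0, q1, 3 * q0, 3 * q1, strand, 0, bits, bits, 1e-5)


class TestBitScore:
    def test_zero_raw_closed_form(self):
        assert bit_score(0, P) == pytest.approx(-math.log(0.041) / math.log(2),
                                                abs=1e-9)
        assert round(bit_score(0, P), 2) == 4.61

    def test_raw_14_is_ten_bits(self):
        assert round(bit_score(14, P), 2) == 10.00

    def test_monotone_in_raw(self):
        assert bit_score(20, P) > bit_score(14, P)

    def test_evalue_decreases_with_score(self):
        assert evalue(30, 100, 1000, P) < evalue(20, 100, 1000, P)


class TestSearchWindow:
    def test_exact_codon_match_scores_raw_14(self):
        hsps = search_window("MKL", "ATGAAACTG", P)
        assert len(hsps) == 1
        h = hsps[0]
        assert (h.strand, h.raw_score) == ("+", 14.0)
        assert (h.sbj_start, h.sbj_end) == (0, 9)

    def test_reverse_complement_gives_minus_hsp(self):
        hsps = search_window("MKL", "CAGTTTCAT", P)
        assert len(hsps) == 1
        assert (hsps[0].strand, hsps[0].raw_score) == ("-", 14.0)

    def test_random_window_respects_evalue_cutoff(self):
        rnd = random.Random(7)
        window = "".join(rnd.choice("ACGT") for _ in range(1500))
        protein = "".join(rnd.choice("ACDEFGHIKLMNPQRSTVWY")
                          for _ in range(200))
        hsps = search_window(protein, window, P)
        assert all(h.evalue <= P.evalue_max for h in hsps)

    def test_planted_copy_recovered_nearly_fully(self, planted, params):
        from tandemscan.genome_io import flanking_window, spliced_dna, translate_cds
        _, genome, truth = planted
        pair = next(a for a in truth.arrays if len(a.cds_ids()) == 2
                    and not a.has_relic())
        a, b = (genome.feature(c) for c in pair.cds_ids())
        prot = translate_cds(genome, a)
        window = flanking_window(genome, a, "downstream")
        hsps = search_window(prot, genome.sequence(window), params)
        best = max(hsps, key=lambda h: h.bit_score)
        assert best.query_length >= 0.95 * len(prot)

    def test_strand_symmetry_on_reverse_complement(self, params):
        from Bio.Seq import Seq
        rnd = random.Random(3)
        core = "ATGGCTAAGCTGGAAGACGTTATCCGTGCT" * 4
        window = ("".join(rnd.choice("ACGT") for _ in range(120)) + core +
                  "".join(rnd.choice("ACGT") for _ in range(120)))
        prot = str(Seq(core).translate())
        fwd = search_window(prot, window, params)
        rev = search_window(prot, str(Seq(window).reverse_complement()), params)
        key = lambda hs: sorted((h.strand, round(h.raw_score, 3)) for h in hs)
        flipped = sorted(("+" if s == "-" else "-", r)
                         for s, r in ((h.strand, round(h.raw_score, 3))
                                      for h in rev))
        assert key(fwd) == flipped

    def test_empty_and_degenerate_windows(self, params):
        assert search_window("MKL", "", params) == []
        assert search_window("MKL", "N" * 600, params) == []

    def test_tblastn_adapter_agrees_on_planted_copy(self, params):
        from Bio.Seq import Seq
        rnd = random.Random(9)
        core = ("ATGGATCGTACCGAACTGGCTAAATGGTCTGAAGAAGTTCATCCGATC" * 6)
        window = ("".join(rnd.choice("ACGT") for _ in range(200)) + core +
                  "".join(rnd.choice("ACGT") for _ in range(200)))
        prot = str(Seq(core).translate())
        internal = search_window(prot, window, params)
        external = search_window_tblastn(prot, window, params)
        bi = max(h.bit_score for h in internal)
        be = max(h.bit_score for h in external)
        assert bi == pytest.approx(be, rel=0.02)
        hi = max(internal, key=lambda h: h.bit_score)
        he = max(external, key=lambda h: h.bit_score)
        assert (hi.strand, hi.sbj_start, hi.sbj_end) == \
               (he.strand, he.sbj_start, he.sbj_end)


def oracle_best_subset(hsps, max_overlap=0.2):
    """Exhaustive maximum-weight subset with pairwise query overlap <= 20%
    of the shorter span (integer arithmetic, independent of the greedy)."""
    def ok(a, b):
        ov = min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
        if ov <= 0:
            return True
        return 5 * ov <= min(a.query_length, b.query_length)

    best = 0.0
    n = len(hsps)
    for mask in range(1 << n):
        subset = [hsps[i] for i in range(n) if mask >> i & 1]
        if all(ok(a, b) for i, a in enumerate(subset)
               for b in subset[i + 1:]):
            best = max(best, sum(h.bit_score for h in subset))
    return best


class TestAggregateTb:
    def test_disjoint_hsps_sum(self):
        assert aggregate_tb([mk_hsp(0, 10, 30.0), mk_hsp(20, 30, 20.0)],
                            "+") == 50.0

    def test_half_overlap_culls_weaker(self):
        assert aggregate_tb([mk_hsp(0, 10, 30.0), mk_hsp(5, 15, 20.0)],
                            "+") == 30.0

    def test_exactly_twenty_percent_overlap_keeps_both(self):
        # spans of length 10 overlapping by 2 -> exactly 20% of the shorter
        assert aggregate_tb([mk_hsp(0, 10, 30.0), mk_hsp(8, 18, 20.0)],
                            "+") == 50.0

    def test_other_strand_ignored(self):
        assert aggregate_tb([mk_hsp(0, 10, 30.0, "-")], "+") == 0.0

    def test_empty_is_zero(self):
        assert aggregate_tb([], "+") == 0.0

    def test_greedy_bounded_by_exhaustive_oracle(self):
        rnd = random.Random(42)
        for _ in range(200):
            n = rnd.randint(1, 6)
            hsps = []
            for _ in range(n):
                q0 = rnd.randint(0, 100)
                q1 = q0 + rnd.randint(5, 40)
                hsps.append(mk_hsp(q0, q1, rnd.uniform(10, 100)))
            greedy = aggregate_tb(hsps, "+")
            opt = oracle_best_subset(hsps)
            assert greedy <= opt + 1e-9

    def test_greedy_optimal_when_all_compatible(self):
        rnd = random.Random(1)
        for _ in range(50):
            hsps, pos = [], 0
            for _ in range(rnd.randint(1, 6)):
                length = rnd.randint(10, 30)
                hsps.append(mk_hsp(pos, pos + length, rnd.uniform(10, 60)))
                pos += length + rnd.randint(0, 5)
            assert aggregate_tb(hsps, "+") == \
                pytest.approx(oracle_best_subset(hsps))
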