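import random

import pytest

from tandemscan.repeats import (dotplot, exact_tandem, find_minisatellite,
                                flag_minisatellite_tgas, quick_tandem_scan)


def brute_force_tandem(dna, min_unit, max_unit):
    """Exhaustive (unit, phase, whole-copy span) consensus-score maximum."""
    n = len(dna)
    best = None
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        for start in range(0, n - 2 * u + 1):
            k = 2
            while start + k * u <= n:
                score = 0
                for col in range(u):
                    counts = {}
                    for row in range(k):
                        c = dna[start + row * u + col]
                        counts[c] = counts.get(c, 0) + 1
                    m = max(counts.values())
                    score += 2 * m - k
                cand = (-score, u, start, k)
                if score > 0 and (best is None or cand < best):
                    best = cand
                k += 1
    return best


class TestQuickScan:
    def test_twelve_mer_repeat_reports_unit_without_multiples(self):
        unit = "ACGTTGCAACGT"
        hits = quick_tandem_scan(unit * 5, threshold=20)
        units = [u for u, _ in hits]
        assert 12 in units
        assert all(u == 12 or u % 12 != 0 for u in units)

    def test_random_sequence_is_quiet(self):
        rnd = random.Random(5)
        dna = "".join(rnd.choice("ACGT") for _ in range(1000))
        assert quick_tandem_scan(dna, threshold=20) == []

    def test_homopolymer_reports_unit_one(self):
        hits = quick_tandem_scan("A" * 80, threshold=20)
        assert hits[0][0] == 1


class TestExactTandem:
    def test_five_exact_copies(self):
        unit = "ACGTTGCAACGT"
        r = exact_tandem(unit * 5)
        assert (r.unit_size, r.copy_count, r.score) == (12, 5, 60)
        assert r.consensus == unit

    def test_one_substitution_costs_two(self):
        unit = "ACGTTGCAACGT"
        s = list(unit * 5)
        s[17] = "G" if s[17] != "G" else "T"
        r = exact_tandem("".join(s))
        assert r.score == 58
        assert r.consensus == unit

    def test_no_positive_score_returns_none(self):
        # at lag 10 every column of the period-4 sequence mismatches, so no
        # unit in range can score above zero
        assert exact_tandem("ACGT" * 5, 10, 10) is None

    def test_quick_gated_scan_quiet_on_random_cds(self):
        rnd = random.Random(2)
        dna = "".join(rnd.choice("ACGT") for _ in range(900))
        assert find_minisatellite(dna) is None

    def test_matches_brute_force_on_random_and_planted_sequences(self):
        rnd = random.Random(12)
        for trial in range(40):
            n = rnd.randint(50, 120)
            dna = list(rnd.choice("ACGT") for _ in range(n))
            if trial % 2 == 0:
                u = rnd.randint(10, 18)
                unit = [rnd.choice("ACGT") for _ in range(u)]
                block = (unit * rnd.randint(2, 3))
                for _ in range(rnd.randint(0, 2)):
                    block[rnd.randrange(len(block))] = rnd.choice("ACGT")
                p = rnd.randint(0, len(dna))
                dna = dna[:p] + block + dna[p:]
            dna = "".join(dna)
            want = brute_force_tandem(dna, 10, 30)
            got = exact_tandem(dna, 10, 30)
            packed = None if got is None else \
                (-got.score, got.unit_size, got.start, got.copy_count)
            assert packed == want, dna


class TestDotplot:
    def test_identical_sequences_main_diagonal(self):
        rnd = random.Random(1)
        s = "".join(rnd.choice("ACGT") for _ in range(100))
        hits = dotplot(s, s)
        main = next(h for h in hits if h.diagonal == 0)
        assert main.length == 100 - 23 + 1
        assert (main.a_start, main.b_start) == (0, 0)

    @staticmethod
    def words_with_identities(k):
        rnd = random.Random(99)
        a = [rnd.choice("ACGT") for _ in range(23)]
        b = []
        idx = list(range(23))
        rnd.shuffle(idx)
        same = set(idx[:k])
        for i, c in enumerate(a):
            if i in same:
                b.append(c)
            else:
                b.append({"A": "C", "C": "G", "G": "T", "T": "A"}[c])
        return "".join(a), "".join(b)

    def test_fifteen_of_twentythree_is_a_dot(self):
        a, b = self.words_with_identities(15)
        assert dotplot(a, b) != []

    def test_fourteen_of_twentythree_is_not(self):
        a, b = self.words_with_identities(14)
        assert dotplot(a, b) == []

    def test_self_comparison_is_symmetric(self):
        rnd = random.Random(4)
        s = "".join(rnd.choice("ACGT") for _ in range(60))
        s = s + s[:30] + s[30:]
        hits = {(h.a_start, h.b_start, h.length) for h in dotplot(s, s)}
        assert all((b, a, l) in hits for a, b, l in hits)

    def test_protein_mode_stringency(self):
        prot = "MSTNPKPQRKTKRNTNRRPQDVKFPGG"
        assert dotplot(prot, prot, window=23, stringency=5,
                       alphabet="protein")


class TestMinisatelliteFlagging:
    def test_true_paralogs_with_repeat_flagged_but_retained(self, minisat_world,
                                                            params):
        from tandemscan.extraction import extract_tgas
        cfg, genome, truth, scores = minisat_world
        res = extract_tgas(scores, genome)
        reports = flag_minisatellite_tgas(res.tgas, genome, scores, params)
        fam_ids = set(truth.arrays[0].cds_ids())
        fam_tga = next(t for t in res.tgas
                       if {m.cds.id for m in t.cds_members()} == fam_ids)
        rep = reports[fam_tga.id]
        assert rep.flagged and not rep.rejected

    def test_shared_long_repeat_between_strangers_rejected(self, minisat_world,
                                                           params):
        from tandemscan.extraction import extract_tgas
        cfg, genome, truth, scores = minisat_world
        res = extract_tgas(scores, genome)
        pair = set(truth.minisat_pair_ids[0])
        fake = next((t for t in res.tgas
                     if {m.cds.id for m in t.cds_members()} == pair), None)
        assert fake is not None, "shared minisatellite did fake a tandem pair"
        reports = flag_minisatellite_tgas(res.tgas, genome, scores, params)
        assert reports[fake.id].flagged
        assert reports[fake.id].rejected

    def test_repeat_free_array_is_unflagged(self, planted, planted_scores,
                                            params):
        from tandemscan.extraction import extract_tgas
        _, genome, _ = planted
        res = extract_tgas(planted_scores, genome)
        reports = flag_minisatellite_tgas(res.tgas, genome, planted_scores,
                                          params)
        assert all(not r.flagged for r in reports.values())

    def test_masking_never_raises_the_facing_scores(self, minisat_world,
                                                    params):
        """Masked re-scored FTB of the repeat-bearing pair stays at or below
        the unmasked values."""
        from tandemscan.extraction import extract_tgas, _positive_score
        from tandemscan.genome_io import (mask_intervals, spliced_dna,
                                          spliced_to_genomic)
        from tandemscan.repeats import find_minisatellite
        from tandemscan.scoring import score_cds
        cfg, genome, truth, scores = minisat_world
        pair = truth.minisat_pair_ids[0]
        ivs = []
        for cid in pair:
            cds = genome.feature(cid)
            hit = find_minisatellite(spliced_dna(genome, cds))
            assert hit is not None
            ivs.extend(spliced_to_genomic(cds, hit.start, hit.end))
        masked = mask_intervals(genome, ivs)
        from tandemscan.scoring import (TbScoreSet, apply_filter, compute_ftb,
                                        compute_tb_scores)
        rows = scores.set_index("cds_id")
        for cid in pair:
            cds = genome.feature(cid)
            tb = compute_tb_scores(masked, cds, params)
            orig_self = float(rows.loc[cid, "tb_self"])
            masked_ftb = apply_filter(
                compute_ftb(TbScoreSet(tb.tb_up_plus, tb.tb_up_minus,
                                       tb.tb_down_plus, tb.tb_down_minus,
                                       orig_self)), orig_self)
            for side in ("up", "down"):
                orig = max(rows.loc[cid, f"f_{side}_plus"],
                           rows.loc[cid, f"f_{side}_minus"])
                new = max(getattr(masked_ftb, f"f_{side}_plus"),
                          getattr(masked_ftb, f"f_{side}_minus"))
                assert new <= orig + 1e-6
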