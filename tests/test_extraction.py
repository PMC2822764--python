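import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tandemscan.extraction import (DEFAULT_THRESHOLD, adjacency,
                                   classify_tga_orientation, curate_tagged,
                                   extract_tgas, flank_scores, is_significant,
                                   orientation_from_strands, Tga, TgaMember)
from tandemscan.genome_io import AnnotatedGenome, CdsFeature


def fake_world(specs):
    """Build a toy genome + score table.  Each spec is a dict with optional
    strand and FTB values; antisymmetry is filled in automatically."""
    feats, rows = [], []
    for i, spec in enumerate(specs):
        strand = spec.get("strand", "+")
        feats.append(CdsFeature(f"g{i}", "chr1",
                                ((2000 * i + 400, 2000 * i + 1600),),
                                strand, rank=i))
        row = {"cds_id": f"g{i}", "chromosome": "chr1", "rank": i,
               "strand": strand, "tb_self": spec.get("tb_self", 500.0),
               "flags": ""}
        for side in ("up", "down"):
            v = spec.get(side, 0.0)
            row[f"f_{side}_plus"] = v
            row[f"f_{side}_minus"] = -v
        for key in ("f_up_plus", "f_up_minus", "f_down_plus", "f_down_minus"):
            if key in spec:
                row[key] = spec[key]
        rows.append(row)
    genome = AnnotatedGenome({"chr1": "A" * (2000 * len(specs) + 2000)},
                             {"chr1": feats})
    return genome, pd.DataFrame(rows)


class TestSignificance:
    def test_plus_strand_significant(self):
        assert is_significant({"f_down_plus": 35.0, "f_down_minus": -35.0},
                              "down") == "+"

    def test_just_below_threshold(self):
        assert is_significant({"f_down_plus": 9.9, "f_down_minus": -9.9},
                              "down") is None

    def test_minus_strand_significant(self):
        assert is_significant({"f_down_plus": -12.0, "f_down_minus": 12.0},
                              "down") == "-"

    def test_adjacency_requires_both_sides(self):
        a = {"f_down_plus": 30.0, "f_down_minus": -30.0}
        b_yes = {"f_up_plus": 20.0, "f_up_minus": -20.0}
        b_no = {"f_up_plus": 5.0, "f_up_minus": -5.0}
        assert adjacency(a, b_yes) == ("+", "+")
        assert adjacency(a, b_no) is None


class TestOrientation:
    @pytest.mark.parametrize("strands,expected", [
        (("+", "+"), "direct_sense"),
        (("-", "-"), "direct_antisense"),
        (("+", "-"), "opposite_convergent"),
        (("-", "+"), "opposite_divergent"),
    ])
    def test_pair_orientation_table(self, strands, expected):
        assert orientation_from_strands(*strands) == expected

    def _tga(self, strands):
        members = [TgaMember("cds",
                             CdsFeature(f"m{i}", "chr1",
                                        ((100 * i, 100 * i + 60),), s, rank=i),
                             strand=s)
                   for i, s in enumerate(strands)]
        return Tga("T", "chr1", members)

    def test_all_direct_sense(self):
        assert classify_tga_orientation(self._tga("+++")) == "direct_sense"

    def test_single_opposite_pair(self):
        assert classify_tga_orientation(self._tga("-+")) == \
            "opposite_divergent"

    def test_direct_plus_opposite_is_mixed(self):
        assert classify_tga_orientation(self._tga("++-")) == "mixed"


class TestAutomaton:
    def test_planted_arrays_recovered_with_sizes(self):
        specs = [{}, {"down": 60}, {"up": 60}, {},
                 {"down": 40}, {"up": 40, "down": 45}, {"up": 45}, {},
                 {"down": 30}, {"up": 30}, {}]
        genome, df = fake_world(specs)
        res = extract_tgas(df, genome)
        sizes = sorted(t.n_cds for t in res.tgas)
        assert sizes == [2, 2, 3]
        assert not res.tagged

    def test_one_spacer_is_bridged(self):
        specs = [{}, {"down": 50}, {}, {"up": 50}, {}]
        genome, df = fake_world(specs)
        res = extract_tgas(df, genome)
        assert len(res.tgas) == 1
        kinds = [m.kind for m in res.tgas[0].members]
        assert kinds == ["cds", "spacer", "cds"]

    def test_spacer_disallowed_breaks_bridge(self):
        specs = [{}, {"down": 50}, {}, {"up": 50}, {}]
        genome, df = fake_world(specs)
        res = extract_tgas(df, genome, allow_spacer=False)
        assert res.tgas == []
        assert {t.cds.id for t in res.tagged} == {"g1", "g3"}

    def test_threshold_boundary_is_inclusive(self):
        genome, df = fake_world([{"down": 10.0}, {"up": 10.0}])
        assert len(extract_tgas(df, genome).tgas) == 1
        genome, df = fake_world([{"down": 9.99}, {"up": 10.0}])
        assert len(extract_tgas(df, genome).tgas) == 0

    def test_isolated_signal_is_tagged_not_arrayed(self):
        genome, df = fake_world([{}, {"down": 25}, {}, {}])
        res = extract_tgas(df, genome)
        assert res.tgas == []
        assert [(t.cds.id, t.reason) for t in res.tagged] == \
            [("g1", "isolated_with_signal")]

    def test_edge_member_with_outward_signal_is_tagged(self):
        specs = [{}, {"up": 30, "down": 60}, {"up": 60}, {}]
        genome, df = fake_world(specs)
        res = extract_tgas(df, genome)
        assert len(res.tgas) == 1
        edge = [t for t in res.tagged if t.reason == "tga_edge_outward_signal"]
        assert [(t.cds.id, t.tga_id) for t in edge] == \
            [("g1", res.tgas[0].id)]

    def test_every_cds_in_exactly_one_place(self):
        specs = [{"down": 60}, {"up": 60}, {"down": 12}, {"up": 12, "down": 12},
                 {"up": 12}, {}, {"down": 33}, {}, {"up": 33}, {"down": 18}]
        genome, df = fake_world(specs)
        res = extract_tgas(df, genome)
        in_tgas = [m.cds.id for t in res.tgas for m in t.members]
        assert len(in_tgas) == len(set(in_tgas))
        tagged = {t.cds.id for t in res.tagged
                  if t.reason == "isolated_with_signal"}
        assert tagged.isdisjoint(in_tgas)
        assert set(in_tgas) | tagged | {"g5", "g7"} == \
            {f"g{i}" for i in range(10)}

    @given(st.lists(st.tuples(st.floats(-40, 40), st.floats(-40, 40)),
                    min_size=2, max_size=12))
    def test_raising_threshold_only_shrinks_the_significant_set(self, values):
        """Every CDS that carries any signal at threshold 15 (whether it
        lands in an array or a tag) already carried one at threshold 10."""
        specs = [{"up": u, "down": d} for u, d in values]
        genome, df = fake_world(specs)
        lo = extract_tgas(df, genome, threshold=10)
        hi = extract_tgas(df, genome, threshold=15)

        def signal_ids(res, thr):
            rows = df.to_dict("records")
            return {r["cds_id"] for r in rows
                    if is_significant(r, "up", thr) is not None
                    or is_significant(r, "down", thr) is not None}

        assert signal_ids(hi, 15) <= signal_ids(lo, 10)
        hi_involved = ({m.cds.id for t in hi.tgas for m in t.members
                        if m.kind == "cds"} |
                       {t.cds.id for t in hi.tagged})
        assert hi_involved <= (signal_ids(lo, 10) |
                               {m.cds.id for t in lo.tgas for m in t.members})

    @given(st.lists(st.tuples(st.floats(-40, 40), st.floats(-40, 40)),
                    min_size=2, max_size=12))
    def test_spacer_free_arrays_unaffected_by_spacer_allowance(self, values):
        specs = [{"up": u, "down": d} for u, d in values]
        genome, df = fake_world(specs)
        with_sp = extract_tgas(df, genome, allow_spacer=True)
        without = extract_tgas(df, genome, allow_spacer=False)
        spacer_free = {frozenset(m.cds.id for m in t.members)
                       for t in with_sp.tgas
                       if all(m.kind == "cds" for m in t.members)}
        no_sp_sets = {frozenset(m.cds.id for m in t.members)
                      for t in without.tgas}
        # arrays that never needed the spacer are identical either way
        assert spacer_free <= no_sp_sets


class TestFlankScores:
    def test_clean_pair_has_zero_outward_scores(self):
        genome, df = fake_world([{}, {"down": 70}, {"up": 70}, {}])
        tga = extract_tgas(df, genome).tgas[0]
        assert tga.s1 == 0.0 and tga.s4 == 0.0
        assert not tga.relic_candidate
        (s2, s3), = tga.pair_scores
        assert (s2, s3) == (70.0, 70.0)

    def test_outward_relic_signal_sets_candidate_flag(self):
        genome, df = fake_world([{}, {"down": 70}, {"up": 70, "down": 28},
                                 {}])
        tga = extract_tgas(df, genome).tgas[0]
        assert tga.s4 == 28.0
        assert tga.relic_candidate


class TestCuration:
    def test_facing_tagged_pair_merges_across_spacer(self):
        genome, df = fake_world([{}, {"down": 20}, {}, {"up": 20}, {}])
        # break the in-pass bridge so both become isolated tags
        res = extract_tgas(df, genome, allow_spacer=False)
        assert len(res.tagged) == 2
        cur = curate_tagged(res.tagged, df, genome, [],
                            dotplot_confirmation=False)
        assert len(cur.new_tgas) == 1
        kinds = [m.kind for m in cur.new_tgas[0].members]
        assert kinds == ["cds", "spacer", "cds"]
        assert not cur.rejected

    def test_planted_relic_confirmed_and_noise_rejected(self, planted,
                                                        planted_scores):
        _, genome, truth = planted
        res = extract_tgas(planted_scores, genome)
        cur = curate_tagged(res.tagged, planted_scores, genome, res.tgas)
        relic_truth = next(m for a in truth.arrays for m in a.members
                           if m.kind == "relic")
        host = next(m.cds_id for a in truth.arrays if a.has_relic()
                    for m in a.members if m.kind == "cds")
        new = [t for t in cur.new_tgas if t.size_class == "1CDS-relic"]
        assert len(new) == 1
        tga = new[0]
        assert {m.cds.id for m in tga.cds_members()} == {host}
        relic = next(m for m in tga.members if m.kind == "relic")
        assert relic.relic_interval.start < relic_truth.end
        assert relic.relic_interval.end > relic_truth.start
        # the background CDS tagged by chance has no intergenic diagonal
        assert any(r.reason == "no_intergenic_diagonal" for r in cur.rejected)
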