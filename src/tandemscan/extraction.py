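"""Tandem gene array extraction from the per-CDS FTB score table.

A single left-to-right pass over the rank-ordered CDSs of each chromosome
assembles maximal runs of "adjacency": CDS a (rank n) and CDS b (rank n+1,
or n+2 across one permitted spacer gene) are adjacent when a's downstream
side and b's upstream side both carry an FTB score at or above the
threshold (default 10).  A run of >= 2 linked CDSs is a tandem gene array
(TGA); its intervening skipped genes are spacer members.

CDSs with significant scores that join no array receive a "relic" tag, as do
array-edge CDSs with an additional outward significant score.  Curation then
either merges facing tagged CDSs into new arrays or confirms a gene relic in
the flanking window by dotplot diagonal detection restricted to intergenic
territory; unconfirmed tags are rejected as false positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .genome_io import (AnnotatedGenome, CdsFeature, GenomicInterval,
                        DEFAULT_MIN_WINDOW, DEFAULT_WINDOW_FACTOR,
                        DOWNSTREAM, UPSTREAM, MINUS, PLUS, flanking_window)
from .repeats import (DNA_DOT_STRINGENCY, DNA_DOT_WINDOW, dotplot)

log = logging.getLogger("tandemscan")

DEFAULT_THRESHOLD = 10.0
#: dotplot curation defaults: minimum diagonal run (dots) and the fraction of
#: the matched window span that must lie outside annotated CDSs
MIN_DIAGONAL_DOTS = 30
MIN_INTERGENIC_FRACTION = 0.5

DIRECT_SENSE = "direct_sense"
DIRECT_ANTISENSE = "direct_antisense"
OPPOSITE_CONVERGENT = "opposite_convergent"
OPPOSITE_DIVERGENT = "opposite_divergent"
MIXED = "mixed"

ISOLATED = "isolated_with_signal"
TGA_EDGE = "tga_edge_outward_signal"


@dataclass
class TgaMember:
    kind: str  # "cds" | "spacer" | "relic"
    cds: CdsFeature | None = None
    relic_interval: GenomicInterval | None = None
    strand: str | None = None

    @property
    def start(self) -> int:
        return self.cds.start if self.cds is not None else self.relic_interval.start

    @property
    def end(self) -> int:
        return self.cds.end if self.cds is not None else self.relic_interval.end


@dataclass
class Tga:
    id: str
    chromosome: str
    members: list[TgaMember]
    size_class: str = "nCDS"
    orientation_class: str = MIXED
    s1: float = 0.0
    s4: float = 0.0
    pair_scores: list[tuple[float, float]] = field(default_factory=list)
    relic_candidate: bool = False

    def cds_members(self) -> list[TgaMember]:
        return [m for m in self.members if m.kind == "cds"]

    def homologous_members(self) -> list[TgaMember]:
        return [m for m in self.members if m.kind != "spacer"]

    @property
    def n_cds(self) -> int:
        return len(self.cds_members())


@dataclass
class TaggedCds:
    cds: CdsFeature
    reason: str  # ISOLATED or TGA_EDGE
    signals: list[tuple[str, str, float]]  # (side, strand, score)
    tga_id: str | None = None


@dataclass
class RejectedTag:
    cds_id: str
    reason: str


@dataclass
class ExtractionResult:
    tgas: list[Tga]
    tagged: list[TaggedCds]


@dataclass
class CurationResult:
    new_tgas: list[Tga]
    extended_tgas: list[Tga]
    confirmed_relics: list[GenomicInterval]
    rejected: list[RejectedTag]


# ---------------------------------------------------------------------------
# significance / adjacency
# ---------------------------------------------------------------------------

def _get(scores, name: str) -> float:
    if isinstance(scores, dict):
        v = scores.get(name, float("nan"))
    else:
        v = getattr(scores, name)
    return float(v)


def is_significant(scores, side: str, threshold: float = DEFAULT_THRESHOLD):
    """Strand whose FTB score on ``side`` ('up'/'down') reaches the
    threshold, else None.  At most one strand per side can be positive."""
    side = {"upstream": "up", "downstream": "down"}.get(side, side)
    p = _get(scores, f"f_{side}_plus")
    m = _get(scores, f"f_{side}_minus")
    if not math.isnan(p) and p >= threshold and (math.isnan(m) or p >= m):
        return PLUS
    if not math.isnan(m) and m >= threshold:
        return MINUS
    return None


def adjacency(scores_a, scores_b, threshold: float = DEFAULT_THRESHOLD):
    """(strand_a_down, strand_b_up) if a's downstream side and b's upstream
    side are both significant, else None."""
    sa = is_significant(scores_a, "down", threshold)
    if sa is None:
        return None
    sb = is_significant(scores_b, "up", threshold)
    if sb is None:
        return None
    return (sa, sb)


def _positive_score(scores, side: str) -> float:
    return max(0.0,
               *(0.0 if math.isnan(v) else v
                 for v in (_get(scores, f"f_{side}_plus"),
                           _get(scores, f"f_{side}_minus"))))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

_ORIENTATION = {(PLUS, PLUS): DIRECT_SENSE,
                (MINUS, MINUS): DIRECT_ANTISENSE,
                (PLUS, MINUS): OPPOSITE_CONVERGENT,
                (MINUS, PLUS): OPPOSITE_DIVERGENT}


def orientation_from_strands(strand_a: str, strand_b: str) -> str:
    return _ORIENTATION[(strand_a, strand_b)]


def pair_orientation(cds_a: CdsFeature, cds_b: CdsFeature) -> str:
    """Orientation class of an (upstream, downstream) pair of annotated CDSs.
    For pairs involving a relic use the member strand inferred from the FTB
    match strand (a relic coded on the same strand as its partner is a direct
    pair)."""
    return orientation_from_strands(cds_a.strand, cds_b.strand)


def classify_tga_orientation(tga: Tga) -> str:
    """Common pair class if all homologous neighbour pairs agree, else mixed."""
    members = tga.homologous_members()
    classes = {orientation_from_strands(a.strand, b.strand)
               for a, b in zip(members, members[1:])}
    if len(classes) == 1:
        return classes.pop()
    return MIXED


# ---------------------------------------------------------------------------
# flank scores
# ---------------------------------------------------------------------------

def flank_scores(tga: Tga, score_lookup: dict,
                 threshold: float = DEFAULT_THRESHOLD) -> Tga:
    """Fill in S1 (outward upstream score of the first member), S4 (outward
    downstream score of the last), and the facing (S2, S3) pair per adjacent
    homologous pair.  S1 or S4 above the threshold marks the array as a
    candidate for starting/ending with a homologous gene relic."""
    members = tga.homologous_members()
    first, last = members[0], members[-1]
    tga.s1 = (_positive_score(score_lookup[first.cds.id], "up")
              if first.kind == "cds" else 0.0)
    tga.s4 = (_positive_score(score_lookup[last.cds.id], "down")
              if last.kind == "cds" else 0.0)
    tga.pair_scores = []
    for a, b in zip(members, members[1:]):
        s2 = (_positive_score(score_lookup[a.cds.id], "down")
              if a.kind == "cds" else float("nan"))
        s3 = (_positive_score(score_lookup[b.cds.id], "up")
              if b.kind == "cds" else float("nan"))
        tga.pair_scores.append((s2, s3))
    tga.relic_candidate = tga.s1 > threshold or tga.s4 > threshold
    return tga


# ---------------------------------------------------------------------------
# the automaton
# ---------------------------------------------------------------------------

def _score_rows(score_df: pd.DataFrame) -> dict[str, dict[int, dict]]:
    by_chrom: dict[str, dict[int, dict]] = {}
    for row in score_df.to_dict("records"):
        by_chrom.setdefault(row["chromosome"], {})[int(row["rank"])] = row
    return by_chrom


def extract_tgas(score_df: pd.DataFrame, genome: AnnotatedGenome,
                 threshold: float = DEFAULT_THRESHOLD,
                 allow_spacer: bool = True) -> ExtractionResult:
    """Assemble TGAs and tag relic-candidate CDSs from a score table.

    Deterministic single pass per chromosome; arrays are maximal runs of
    adjacency, a CDS adjacent on both sides occupies a middle position and
    never splits an array.
    """
    rows_by_chrom = _score_rows(score_df)
    tgas: list[Tga] = []
    tagged: list[TaggedCds] = []
    counter = 0

    for chrom in sorted(genome.features):
        feats = genome.features[chrom]
        rows = rows_by_chrom.get(chrom, {})
        k = len(feats)

        def adj(i: int, j: int):
            if i not in rows or j not in rows:
                return None
            return adjacency(rows[i], rows[j], threshold)

        def step(j: int):
            if adj(j, j + 1) is not None:
                return j + 1
            if allow_spacer and adj(j, j + 2) is not None:
                return j + 2
            return None

        in_tga: set[int] = set()
        i = 0
        while i < k - 1:
            nxt = step(i)
            if nxt is None:
                i += 1
                continue
            chain = [i]
            while nxt is not None:
                chain.append(nxt)
                nxt = step(nxt)
            counter += 1
            chain_set = set(chain)
            members = []
            for r in range(chain[0], chain[-1] + 1):
                kind = "cds" if r in chain_set else "spacer"
                members.append(TgaMember(kind=kind, cds=feats[r],
                                         strand=feats[r].strand))
                in_tga.add(r)
            tga = Tga(id=f"TGA{counter:04d}", chromosome=chrom, members=members)
            tga.size_class = "nCDS"
            tga.orientation_class = classify_tga_orientation(tga)
            score_lookup = {feats[r].id: rows[r]
                            for r in range(chain[0], chain[-1] + 1) if r in rows}
            flank_scores(tga, score_lookup, threshold)
            tgas.append(tga)
            i = chain[-1] + 1

        # relic tags
        for r in range(k):
            if r in in_tga or r not in rows:
                continue
            signals = []
            for side in ("up", "down"):
                s = is_significant(rows[r], side, threshold)
                if s is not None:
                    signals.append((side, s, _positive_score(rows[r], side)))
            if signals:
                tagged.append(TaggedCds(feats[r], ISOLATED, signals))

    for tga in tgas:
        rows = rows_by_chrom.get(tga.chromosome, {})
        first = tga.members[0]
        last = tga.members[-1]
        for member, side in ((first, "up"), (last, "down")):
            if member.kind != "cds":
                continue
            row = rows.get(member.cds.rank)
            if row is None:
                continue
            s = is_significant(row, side, threshold)
            if s is not None:
                tagged.append(TaggedCds(member.cds, TGA_EDGE,
                                        [(side, s, _positive_score(row, side))],
                                        tga_id=tga.id))
    return ExtractionResult(tgas, tagged)


# ---------------------------------------------------------------------------
# curation of tagged CDSs
# ---------------------------------------------------------------------------

def _cds_coverage(genome: AnnotatedGenome, iv: GenomicInterval) -> int:
    covered = 0
    for f in genome.features.get(iv.chromosome, ()):
        covered += f.span.overlap(iv)
    return min(covered, len(iv))


def confirm_relic(genome: AnnotatedGenome, cds: CdsFeature, side: str,
                  strand: str,
                  factor: float = DEFAULT_WINDOW_FACTOR,
                  min_len: int = DEFAULT_MIN_WINDOW,
                  dot_window: int = DNA_DOT_WINDOW,
                  dot_stringency: int = DNA_DOT_STRINGENCY,
                  min_diagonal: int = MIN_DIAGONAL_DOTS,
                  min_intergenic_fraction: float = MIN_INTERGENIC_FRACTION
                  ) -> GenomicInterval | None:
    """Dotplot screen of a tagged CDS against its significant flank window.

    A qualifying diagonal (>= ``min_diagonal`` consecutive dots at DNA
    window/stringency defaults 23/15) whose window span lies mostly
    (>= ``min_intergenic_fraction``) outside annotated CDSs confirms a gene
    relic; the returned interval is the matched span in chromosome
    coordinates.  ``strand`` is the FTB match strand: a relic on the same
    strand as its source CDS aligns to the window as-is, an opposite-strand
    relic aligns to its reverse complement.
    """
    side = {"up": UPSTREAM, "down": DOWNSTREAM}.get(side, side)
    window = flanking_window(genome, cds, side, factor, min_len)
    wseq = genome.sequence(window)
    if len(wseq) < dot_window:
        return None
    cseq = genome.sequence(cds.span)
    same = (strand == cds.strand)
    target = wseq if same else str(Seq(wseq).reverse_complement())
    for hit in dotplot(cseq, target, dot_window, dot_stringency):
        if hit.length < min_diagonal:
            break
        b0, b1 = hit.b_start, hit.b_end
        if not same:
            b0, b1 = len(wseq) - hit.b_end, len(wseq) - hit.b_start
        iv = GenomicInterval(window.chromosome,
                             window.start + b0, window.start + b1)
        intergenic = 1.0 - _cds_coverage(genome, iv) / len(iv)
        if intergenic >= min_intergenic_fraction:
            return iv
    return None


def curate_tagged(tagged: list[TaggedCds], score_df: pd.DataFrame,
                  genome: AnnotatedGenome, tgas: list[Tga] | None = None,
                  threshold: float = DEFAULT_THRESHOLD,
                  factor: float = DEFAULT_WINDOW_FACTOR,
                  min_len: int = DEFAULT_MIN_WINDOW,
                  merge_tagged_pairs: bool = True,
                  dotplot_confirmation: bool = True,
                  min_diagonal: int = MIN_DIAGONAL_DOTS,
                  min_intergenic_fraction: float = MIN_INTERGENIC_FRACTION
                  ) -> CurationResult:
    """Automated curation of relic-tagged CDSs.

    (i) facing pairs of isolated tagged CDSs across at most one spacer merge
    into new TGAs; (ii) remaining tags are screened by dotplot against their
    significant flank window -- a qualifying intergenic diagonal confirms a
    relic (a 1CDS-relic TGA, or an nCDSs-relic extension for array-edge
    tags); (iii) anything else is rejected as a false positive.
    """
    tgas = tgas or []
    rows_by_chrom = _score_rows(score_df)
    score_by_id = {r["cds_id"]: r for c in rows_by_chrom.values()
                   for r in c.values()}
    new_tgas: list[Tga] = []
    extended: list[Tga] = []
    confirmed: list[GenomicInterval] = []
    rejected: list[RejectedTag] = []
    counter = sum(1 for _ in tgas)

    isolated = [t for t in tagged if t.reason == ISOLATED]
    edge = [t for t in tagged if t.reason == TGA_EDGE]
    consumed: set[str] = set()

    if merge_tagged_pairs:
        by_chrom: dict[str, list[TaggedCds]] = {}
        for t in isolated:
            by_chrom.setdefault(t.cds.chromosome, []).append(t)
        for chrom, tags in sorted(by_chrom.items()):
            tags.sort(key=lambda t: t.cds.rank)
            feats = genome.features[chrom]
            idx = 0
            while idx < len(tags) - 1:
                a, b = tags[idx], tags[idx + 1]
                gap = b.cds.rank - a.cds.rank
                link = (1 <= gap <= 2 and
                        adjacency(score_by_id[a.cds.id],
                                  score_by_id[b.cds.id], threshold))
                if link:
                    counter += 1
                    members = [TgaMember("cds", a.cds, strand=a.cds.strand)]
                    if gap == 2:
                        sp = feats[a.cds.rank + 1]
                        members.append(TgaMember("spacer", sp, strand=sp.strand))
                    members.append(TgaMember("cds", b.cds, strand=b.cds.strand))
                    tga = Tga(id=f"TGA{counter:04d}", chromosome=chrom,
                              members=members)
                    tga.orientation_class = classify_tga_orientation(tga)
                    flank_scores(tga, score_by_id, threshold)
                    new_tgas.append(tga)
                    consumed.update((a.cds.id, b.cds.id))
                    idx += 2
                else:
                    idx += 1

    if dotplot_confirmation:
        tga_by_id = {t.id: t for t in tgas}
        for tag in isolated:
            if tag.cds.id in consumed:
                continue
            iv = None
            for side, strand, _score in tag.signals:
                iv = confirm_relic(genome, tag.cds, side, strand, factor,
                                   min_len, min_diagonal=min_diagonal,
                                   min_intergenic_fraction=min_intergenic_fraction)
                if iv is not None:
                    relic_strand = strand
                    break
            if iv is None:
                rejected.append(RejectedTag(tag.cds.id, "no_intergenic_diagonal"))
                continue
            confirmed.append(iv)
            counter += 1
            members = [TgaMember("cds", tag.cds, strand=tag.cds.strand),
                       TgaMember("relic", relic_interval=iv, strand=relic_strand)]
            members.sort(key=lambda m: m.start)
            tga = Tga(id=f"TGA{counter:04d}", chromosome=tag.cds.chromosome,
                      members=members, size_class="1CDS-relic")
            tga.orientation_class = classify_tga_orientation(tga)
            flank_scores(tga, score_by_id, threshold)
            new_tgas.append(tga)
        for tag in edge:
            side, strand, _score = tag.signals[0]
            iv = confirm_relic(genome, tag.cds, side, strand, factor, min_len,
                               min_diagonal=min_diagonal,
                               min_intergenic_fraction=min_intergenic_fraction)
            if iv is None:
                rejected.append(RejectedTag(tag.cds.id, "no_intergenic_diagonal"))
                continue
            confirmed.append(iv)
            tga = tga_by_id.get(tag.tga_id)
            if tga is None:
                continue
            tga.members.append(TgaMember("relic", relic_interval=iv,
                                         strand=strand))
            tga.members.sort(key=lambda m: m.start)
            tga.size_class = "nCDSs-relic"
            tga.orientation_class = classify_tga_orientation(tga)
            if tga not in extended:
                extended.append(tga)
    else:
        for tag in isolated + edge:
            if tag.cds.id not in consumed:
                rejected.append(RejectedTag(tag.cds.id, "curation_disabled"))

    return CurationResult(new_tgas, extended, confirmed, rejected)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _member_str(m: TgaMember) -> str:
    if m.kind == "relic":
        return f"relic:{m.relic_interval.start}-{m.relic_interval.end}:{m.strand}"
    return f"{m.cds.id}:{m.kind}:{m.cds.start}-{m.cds.end}:{m.strand}"


def write_tgas(tgas: list[Tga], path) -> None:
    with open(path, "w") as fh:
        fh.write("#tga_id\tchromosome\tn_cds\tsize_class\torientation_class\t"
                 "s1\ts4\tpair_scores\tmembers\n")
        for t in tgas:
            pairs = "|".join(f"{a:.2f}/{b:.2f}" for a, b in t.pair_scores)
            members = "|".join(_member_str(m) for m in t.members)
            fh.write(f"{t.id}\t{t.chromosome}\t{t.n_cds}\t{t.size_class}\t"
                     f"{t.orientation_class}\t{t.s1:.2f}\t{t.s4:.2f}\t"
                     f"{pairs}\t{members}\n")


def write_relics_bed(tgas: list[Tga], path) -> None:
    """BED of relic member intervals (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for t in tgas:
            for m in t.members:
                if m.kind == "relic":
                    fh.write(f"{t.chromosome}\t{m.relic_interval.start}\t"
                             f"{m.relic_interval.end}\t{t.id}_relic\t0\t"
                             f"{m.strand}\n")


def write_rejected(rejected: list[RejectedTag], path) -> None:
    with open(path, "w") as fh:
        fh.write("#cds_id\treason\n")
        for r in rejected:
            fh.write(f"{r.cds_id}\t{r.reason}\n")
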