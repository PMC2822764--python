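"""Genome / annotation I/O, CDS translation and flanking search windows.

Coordinate conventions
----------------------
External files (GFF3, annotation TSV) use 1-based inclusive coordinates;
everything in memory is 0-based half-open.  The readers and writers below are
the only place where the shift happens.

"Upstream" and "downstream" are *chromosomal-coordinate* directions (toward
lower / higher coordinates), not gene-orientation directions.  Both strands of
every window are searched downstream of here, so the two conventions are
observationally equivalent; the chromosomal one keeps the array-assembly
automaton simple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("tandemscan")

PLUS = "+"
MINUS = "-"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

#: default flanking-window sizing: window length = max(FACTOR * L_cds, MIN_WINDOW)
DEFAULT_WINDOW_FACTOR = 3.0
DEFAULT_MIN_WINDOW = 1500


class AnnotationError(ValueError):
    """Raised when an annotation does not fit the sequence it annotates."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named chromosome.

    ``start == end`` denotes an empty interval (a flanking window clipped away
    entirely at a chromosome edge).
    """

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class CdsFeature:
    """One annotated protein-coding sequence.

    ``exons`` are 0-based half-open intervals in ascending order; ``rank`` is
    the position of the CDS in the coordinate-sorted gene order of its
    chromosome (the neighbour index used by the array-assembly automaton).
    """

    id: str
    chromosome: str
    exons: tuple[tuple[int, int], ...]
    strand: str
    rank: int = -1
    translatable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise AnnotationError(f"{self.id}: CDS needs at least one exon")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if b <= a:
                raise AnnotationError(f"{self.id}: empty exon [{a}, {b})")
        for (_, b), (a2, _) in zip(exons, exons[1:]):
            if a2 < b:
                raise AnnotationError(f"{self.id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus rank-ordered CDS features per chromosome."""

    chromosomes: dict[str, str]
    features: dict[str, list[CdsFeature]]
    genetic_code: int = 1

    def all_features(self) -> list[CdsFeature]:
        return [f for chrom in sorted(self.features) for f in self.features[chrom]]

    def feature(self, cds_id: str) -> CdsFeature:
        for f in self.all_features():
            if f.id == cds_id:
                return f
        raise KeyError(cds_id)

    def n_cds(self) -> int:
        return sum(len(v) for v in self.features.values())

    def sequence(self, interval: GenomicInterval) -> str:
        return self.chromosomes[interval.chromosome][interval.start:interval.end]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _assign_ranks(features: dict[str, list[CdsFeature]]) -> None:
    for chrom, feats in features.items():
        feats.sort(key=lambda f: (f.start, f.end, f.id))
        for rank, f in enumerate(feats):
            f.rank = rank


def _check_and_flag(genome: AnnotatedGenome) -> None:
    for chrom, feats in genome.features.items():
        if chrom not in genome.chromosomes:
            bad = feats[0].id if feats else "?"
            raise AnnotationError(
                f"feature {bad!r} annotated on unknown chromosome {chrom!r}")
        clen = len(genome.chromosomes[chrom])
        for f in feats:
            if f.end > clen:
                raise AnnotationError(
                    f"feature {f.id!r} exceeds chromosome {chrom!r} length {clen}")
            trim = f.spliced_length % 3
            if trim:
                log.warning("%s: spliced length %d not a multiple of 3; "
                            "trailing %d base(s) trimmed for translation",
                            f.id, f.spliced_length, trim)
            if f.spliced_length - trim < 3:
                log.warning("%s: too short to translate; flagged untranslatable", f.id)
                f.translatable = False


def read_annotation_tsv(path: str | Path) -> dict[str, list[CdsFeature]]:
    """Read the simple 4-column annotation dialect.

    Columns (tab-separated): id, chromosome, strand, exons, where exons is a
    comma-separated list of 1-based inclusive ``start-end`` intervals.
    """
    features: dict[str, list[CdsFeature]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationError(f"annotation line needs 4 columns: {line!r}")
            cid, chrom, strand, exon_str = parts[:4]
            exons = []
            for token in exon_str.split(","):
                a, b = token.split("-")
                exons.append((int(a) - 1, int(b)))  # 1-based incl -> 0-based half-open
            features.setdefault(chrom, []).append(
                CdsFeature(cid, chrom, tuple(exons), strand))
    return features


def read_annotation_gff3(path: str | Path) -> dict[str, list[CdsFeature]]:
    """Read CDS features from GFF3, grouping segments by their Parent.

    Only the first isoform per locus is kept: if two groups overlap on the
    same chromosome the later-starting one is dropped with a log message.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    groups: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id or "cds"])[0]
        key = (cds.seqid, parent)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(cds)

    features: dict[str, list[CdsFeature]] = {}
    kept: dict[str, list[CdsFeature]] = {}
    for (chrom, parent) in order:
        segs = groups[(chrom, parent)]
        exons = tuple(sorted((s.start - 1, s.end) for s in segs))
        feat = CdsFeature(parent, chrom, exons, segs[0].strand)
        clash = next((k for k in kept.get(chrom, ())
                      if k.span.overlap(feat.span) > 0), None)
        if clash is not None:
            log.info("GFF3: dropping isoform %s overlapping %s", parent, clash.id)
            continue
        kept.setdefault(chrom, []).append(feat)
        features.setdefault(chrom, []).append(feat)
    return features


def read_genome(fasta_path: str | Path, annotation_path: str | Path,
                genetic_code: int = 1) -> AnnotatedGenome:
    """Load a genome FASTA plus a CDS annotation (GFF3 or TSV by extension)."""
    chromosomes = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not chromosomes:
        raise AnnotationError(f"no FASTA records in {fasta_path}")
    apath = Path(annotation_path)
    if apath.suffix.lower() in (".gff", ".gff3"):
        features = read_annotation_gff3(apath)
    else:
        features = read_annotation_tsv(apath)
    for chrom in chromosomes:
        features.setdefault(chrom, [])
    genome = AnnotatedGenome(chromosomes, features, genetic_code=genetic_code)
    _check_and_flag(genome)
    _assign_ranks(genome.features)
    return genome


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path,
                 annotation_path: str | Path) -> None:
    """Write FASTA + TSV annotation; round-trips bit-identically via read_genome."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(genome.chromosomes.items())]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("#cds_id\tchromosome\tstrand\texons\n")
        for f in genome.all_features():
            exon_str = ",".join(f"{a + 1}-{b}" for a, b in f.exons)
            fh.write(f"{f.id}\t{f.chromosome}\t{f.strand}\t{exon_str}\n")


def write_annotation_gff3(genome: AnnotatedGenome, path: str | Path,
                          source: str = "tandemscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.all_features():
            fh.write(f"{f.chromosome}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t"
                     f"{f.strand}\t.\tID=gene:{f.id}\n")
            fh.write(f"{f.chromosome}\t{source}\tmRNA\t{f.start + 1}\t{f.end}\t.\t"
                     f"{f.strand}\t.\tID={f.id};Parent=gene:{f.id}\n")
            for a, b in f.exons:
                fh.write(f"{f.chromosome}\t{source}\tCDS\t{a + 1}\t{b}\t.\t"
                         f"{f.strand}\t0\tParent={f.id}\n")


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def spliced_dna(genome: AnnotatedGenome, cds: CdsFeature) -> str:
    """Spliced coding DNA in 5'->3' coding orientation (minus strand CDSs are
    reverse-complemented), trailing partial codon trimmed."""
    chrom = genome.chromosomes[cds.chromosome]
    seq = "".join(chrom[a:b] for a, b in cds.exons)
    if cds.strand == MINUS:
        seq = str(Seq(seq).reverse_complement())
    trim = len(seq) % 3
    if trim:
        seq = seq[:-trim]
    return seq


def translate_cds(genome: AnnotatedGenome, cds: CdsFeature) -> str:
    """Protein sequence of a CDS; internal stops rendered '*', terminal stop
    dropped.  Raises on features flagged untranslatable."""
    if not cds.translatable:
        raise AnnotationError(f"{cds.id}: untranslatable feature")
    seq = spliced_dna(genome, cds)
    prot = str(Seq(seq).translate(table=genome.genetic_code))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def spliced_to_genomic(cds: CdsFeature, lo: int, hi: int) -> list[GenomicInterval]:
    """Map a half-open interval in spliced coding coordinates (5'->3' of the
    coding strand) to chromosome intervals."""
    if not 0 <= lo <= hi <= cds.spliced_length:
        raise ValueError(f"spliced interval [{lo}, {hi}) out of bounds")
    exons = cds.exons if cds.strand == PLUS else tuple(reversed(cds.exons))
    out: list[GenomicInterval] = []
    offset = 0
    for a, b in exons:
        elen = b - a
        s, e = max(lo, offset), min(hi, offset + elen)
        if s < e:
            if cds.strand == PLUS:
                out.append(GenomicInterval(cds.chromosome,
                                           a + (s - offset), a + (e - offset)))
            else:
                out.append(GenomicInterval(cds.chromosome,
                                           b - (e - offset), b - (s - offset)))
        offset += elen
    out.sort(key=lambda iv: iv.start)
    return out


def mask_intervals(genome: AnnotatedGenome,
                   intervals: list[GenomicInterval]) -> AnnotatedGenome:
    """Copy of the genome with the given intervals hard-masked to N."""
    chroms = dict(genome.chromosomes)
    for iv in intervals:
        seq = chroms[iv.chromosome]
        chroms[iv.chromosome] = (seq[:iv.start] + "N" * len(iv) + seq[iv.end:])
    return AnnotatedGenome(chroms, genome.features, genome.genetic_code)


# ---------------------------------------------------------------------------
# flanking windows
# ---------------------------------------------------------------------------

def flanking_window(genome: AnnotatedGenome, cds: CdsFeature, side: str,
                    factor: float = DEFAULT_WINDOW_FACTOR,
                    min_len: int = DEFAULT_MIN_WINDOW) -> GenomicInterval:
    """Search window adjacent to a CDS on one chromosomal side.

    Window length is ``max(factor * spliced CDS length, min_len)``, measured
    from the CDS's outermost genomic coordinate (introns lie inside the
    excluded span), silently truncated at chromosome ends.
    """
    if side not in (UPSTREAM, DOWNSTREAM):
        raise ValueError(f"side must be {UPSTREAM!r} or {DOWNSTREAM!r}")
    wlen = max(int(round(factor * cds.spliced_length)), int(min_len))
    clen = len(genome.chromosomes[cds.chromosome])
    if side == UPSTREAM:
        lo = max(0, cds.start - wlen)
        iv = GenomicInterval(cds.chromosome, lo, cds.start)
    else:
        hi = min(clen, cds.end + wlen)
        iv = GenomicInterval(cds.chromosome, cds.end, hi)
    if len(iv) < wlen:
        log.debug("window for %s (%s) truncated to %d bp at chromosome edge",
                  cds.id, side, len(iv))
    return iv
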