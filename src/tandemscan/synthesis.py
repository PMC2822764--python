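"""Synthetic annotated genomes with planted tandem gene arrays.

The generator emulates a compact hemiascomycete-like genome: protein-coding
genes averaging ~1.38 kb packed at roughly one gene per 2 kb (mean
intergenic distance ~0.62 kb), single-exon by default.  Background genes are
drawn by codon sampling from a fixed yeast-like codon-usage table, which
gives realistic base/amino-acid composition while keeping genes mutually
dissimilar.  On this background the generator plants, per a declarative
plan:

* tandem arrays of 2..n gene copies at controlled amino-acid divergence,
  with per-copy strand orientations and optional single spacer genes;
* gene relics: diverged copies degraded by premature stops, frameshifts and
  truncation until no open reading frame covers half the original gene,
  placed in intergenic territory and absent from the annotation;
* dispersed paralog families (copies far apart on the chromosome);
* intragenic minisatellites, either shared by true paralogs or planted into
  two unrelated neighbouring genes to fake a tandem pair.

Everything is deterministic given the seed, and every planted object is
recorded in a machine-readable truth ledger against which recovery is
scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import (AnnotatedGenome, CdsFeature, _assign_ranks,
                        write_annotation_gff3, write_genome)

log = logging.getLogger("tandemscan")

# S. cerevisiae-like codon usage (relative weights; all 61 sense codons)
CODON_WEIGHTS = {
    "TTT": 26, "TTC": 18, "TTA": 26, "TTG": 27, "CTT": 12, "CTC": 5,
    "CTA": 13, "CTG": 10, "ATT": 30, "ATC": 17, "ATA": 18, "ATG": 21,
    "GTT": 22, "GTC": 11, "GTA": 12, "GTG": 11, "TCT": 23, "TCC": 14,
    "TCA": 19, "TCG": 9, "AGT": 14, "AGC": 10, "CCT": 13, "CCC": 7,
    "CCA": 18, "CCG": 5, "ACT": 20, "ACC": 13, "ACA": 18, "ACG": 8,
    "GCT": 21, "GCC": 12, "GCA": 16, "GCG": 6, "TAT": 19, "TAC": 15,
    "CAT": 14, "CAC": 8, "CAA": 27, "CAG": 12, "AAT": 36, "AAC": 25,
    "AAA": 42, "AAG": 31, "GAT": 38, "GAC": 20, "GAA": 45, "GAG": 19,
    "TGT": 8, "TGC": 5, "TGG": 10, "CGT": 6, "CGC": 3, "CGA": 3,
    "CGG": 2, "AGA": 21, "AGG": 9, "GGT": 24, "GGC": 10, "GGA": 11,
    "GGG": 6,
}
_CODONS = sorted(CODON_WEIGHTS)
_WEIGHTS = np.array([CODON_WEIGHTS[c] for c in _CODONS], dtype=float)
_WEIGHTS /= _WEIGHTS.sum()

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_OF = dict(_TABLE.forward_table)
_SYNONYMS: dict[str, list[str]] = {}
for _c in _CODONS:
    _SYNONYMS.setdefault(_AA_OF[_c], []).append(_c)

STOP = "TAA"
_BASE_WEIGHTS = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}


# ---------------------------------------------------------------------------
# plans and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelicPlan:
    """A degenerated extra copy planted in intergenic territory."""
    position: str = "end"       # "start" (upstream of array) or "end"
    identity: float = 78.0      # aa divergence applied before degradation
    n_disruptions: int = 2
    truncate_frac: float = 0.15
    strand: str = "+"


@dataclass(frozen=True)
class ArrayPlan:
    size: int
    identity: float = 90.0
    orientations: tuple[str, ...] | None = None
    spacers: tuple[int, ...] = ()   # gap index i = one spacer between copies i, i+1
    relic: RelicPlan | None = None
    minisat: tuple[int, int] | None = None  # (unit bp, copies) in the founder

    def __post_init__(self):
        n_members = self.size + (1 if self.relic else 0)
        if n_members < 2:
            raise ValueError("array needs >= 2 members (counting relics)")
        if not 30 <= self.identity <= 100:
            raise ValueError("target identity must be in [30, 100]")
        if self.orientations is not None and len(self.orientations) != self.size:
            raise ValueError("orientations must match array size")
        if any(g < 0 or g >= self.size - 1 for g in self.spacers):
            raise ValueError("spacer gap index out of range")


@dataclass(frozen=True)
class DispersedPlan:
    size: int
    identity: float = 70.0


@dataclass(frozen=True)
class MinisatPairPlan:
    """Two unrelated neighbouring genes sharing one long minisatellite."""
    unit_size: int = 30
    copies: int = 12


@dataclass
class SynthConfig:
    seed: int = 0
    n_chromosomes: int = 1
    n_background: int = 60
    gene_len_mean: float = 1380.0
    gene_len_shape: float = 6.0
    gene_len_min: int = 300
    intergenic_mean: float = 620.0
    intergenic_shape: float = 2.0
    intergenic_min: int = 150
    arrays: list[ArrayPlan] = field(default_factory=list)
    dispersed: list[DispersedPlan] = field(default_factory=list)
    minisat_pairs: list[MinisatPairPlan] = field(default_factory=list)
    intron_fraction: float = 0.0    # fraction of background genes with 1 intron
    intron_length: int = 90
    genetic_code: int = 1


@dataclass
class PlantedMember:
    kind: str               # cds | spacer | relic
    cds_id: str | None
    chromosome: str
    start: int
    end: int
    strand: str
    aa_identity: float      # vs family founder (nan for spacers)
    dna_identity: float


@dataclass
class PlantedArray:
    family_id: str
    chromosome: str
    members: list[PlantedMember]

    def cds_ids(self) -> list[str]:
        return [m.cds_id for m in self.members if m.kind == "cds"]

    def has_relic(self) -> bool:
        return any(m.kind == "relic" for m in self.members)


@dataclass
class PlantedMinisat:
    host_cds_id: str
    unit_size: int
    copies: int
    start: int              # spliced coding coordinates within the gene
    end: int


@dataclass
class PlantedFamily:
    family_id: str
    cds_ids: list[str]
    identity: float


@dataclass
class SyntheticTruth:
    seed: int
    arrays: list[PlantedArray] = field(default_factory=list)
    minisats: list[PlantedMinisat] = field(default_factory=list)
    dispersed: list[PlantedFamily] = field(default_factory=list)
    minisat_pair_ids: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list("ACGT"))
    w = np.array([_BASE_WEIGHTS[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=length, p=w))


def random_gene(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + codon-sampled interior + stop; no internal stops by construction."""
    interior = rng.choice(len(_CODONS), size=max(1, n_codons), p=_WEIGHTS)
    return "ATG" + "".join(_CODONS[i] for i in interior) + STOP


def _protein(dna: str) -> str:
    return str(Seq(dna).translate(table=1)).rstrip("*")


def protein_identity(a: str, b: str) -> float:
    """Positionwise percent identity of two equal-length proteins."""
    if len(a) != len(b):
        raise ValueError("positionwise identity needs equal lengths")
    same = sum(x == y for x, y in zip(a, b))
    return 100.0 * same / len(a)


def dna_identity(a: str, b: str, mode: str = "NW") -> float:
    """Percent identity via edit distance (edlib).  ``mode="NW"`` is global;
    ``mode="HW"`` aligns ``a`` to its best-matching infix of ``b`` (the right
    measure for a truncated relic against its full-length source)."""
    d = edlib.align(a, b, task="distance", mode=mode)["editDistance"]
    denom = len(a) if mode == "HW" else max(len(a), len(b))
    return 100.0 * (1.0 - d / denom)


def mutate_copy(dna: str, target_identity_pct: float,
                rng: np.random.Generator, p_synonymous: float = 0.5) -> str:
    """Codon-level substitutions until the translated identity to the input
    drops to ``target_identity_pct`` (within ~2 points; substitutions only,
    so the reading frame and length are preserved)."""
    if not 30 <= target_identity_pct <= 100:
        raise ValueError("target identity must be in [30, 100]")
    if target_identity_pct >= 100:
        return dna
    codons = [dna[i:i + 3] for i in range(0, len(dna) - len(dna) % 3, 3)]
    orig_aa = [_AA_OF.get(c, "*") for c in codons]
    cur = list(codons)
    n_aa = len(codons) - 1  # final stop not part of the protein
    matches = n_aa
    identity = 100.0
    guard = 0
    while identity > target_identity_pct and guard < 200 * len(codons):
        guard += 1
        idx = int(rng.integers(1, len(codons) - 1))  # keep start + stop intact
        aa = _AA_OF.get(cur[idx])
        if aa is None:
            continue
        if rng.random() < p_synonymous and len(_SYNONYMS[aa]) > 1:
            choices = [c for c in _SYNONYMS[aa] if c != cur[idx]]
        else:
            choices = [c for c in _CODONS if _AA_OF[c] != aa]
        new = choices[int(rng.integers(0, len(choices)))]
        was_match = _AA_OF[cur[idx]] == orig_aa[idx]
        cur[idx] = new
        is_match = _AA_OF[new] == orig_aa[idx]
        matches += int(is_match) - int(was_match)
        identity = 100.0 * matches / n_aa
    return "".join(cur)


def _longest_orf_span(dna: str) -> tuple[int, int]:
    """(length bp, start) of the longest stop-free stretch over the three
    forward frames."""
    best, best_start = 0, 0
    for f in range(3):
        run, run_start = 0, f
        for i in range(f, len(dna) - 2, 3):
            if dna[i:i + 3] in _TABLE.stop_codons:
                run, run_start = 0, i + 3
            else:
                run += 3
                if run > best:
                    best, best_start = run, run_start
    return best, best_start


def _longest_orf(dna: str) -> int:
    return _longest_orf_span(dna)[0]


def degrade_to_relic(dna: str, n_disruptions: int = 2,
                     truncate_frac: float = 0.15,
                     rng: np.random.Generator | None = None) -> str:
    """Degrade a gene copy into a relic: premature stops and/or single-base
    frameshifts (plus optional 3' truncation) until no open reading frame
    covers half of the original length."""
    if n_disruptions < 1:
        raise ValueError("a relic needs at least one disruption")
    rng = rng if rng is not None else np.random.default_rng(0)
    n_codons = len(dna) // 3
    lo, hi = max(1, n_codons // 10), max(2, (9 * n_codons) // 10)
    k = min(n_disruptions, hi - lo)
    sites = sorted(rng.choice(np.arange(lo, hi), size=k, replace=False),
                   reverse=True)
    seq = dna
    for codon_idx in sites:
        pos = codon_idx * 3
        if rng.random() < 0.5:
            seq = seq[:pos] + STOP + seq[pos + 3:]          # nonsense
        else:
            seq = seq[:pos] + seq[pos + 1:]                 # -1 frameshift
    if truncate_frac > 0:
        keep = max(30, int(len(seq) * (1.0 - truncate_frac)))
        seq = seq[:keep]
    limit = 0.5 * len(dna)
    for _ in range(12):
        length, start = _longest_orf_span(seq)
        if length < limit:
            break
        # terminate the offending frame at the middle of its open stretch
        mid = start + 3 * ((length // 3) // 2)
        seq = seq[:mid] + STOP + seq[mid + 3:]
    return seq


def insert_minisatellite(dna: str, unit_size: int, copies: int,
                         rng: np.random.Generator) -> tuple[str, int, int]:
    """Insert an in-frame tandem repeat (unit length a multiple of 3, built
    from sense codons) at the midpoint codon boundary.  Returns
    (new_dna, start, end) with the repeat span in spliced coordinates."""
    if unit_size % 3 != 0:
        raise ValueError("unit size must be a multiple of 3 to stay in frame")
    unit_codons = rng.choice(len(_CODONS), size=unit_size // 3, p=_WEIGHTS)
    unit = "".join(_CODONS[i] for i in unit_codons)
    block = unit * copies
    at = 3 * ((len(dna) // 2) // 3)
    return dna[:at] + block + dna[at:], at, at + len(block)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _gene_length_codons(rng: np.random.Generator, cfg: SynthConfig) -> int:
    L = rng.gamma(cfg.gene_len_shape, cfg.gene_len_mean / cfg.gene_len_shape)
    return max(cfg.gene_len_min, int(L)) // 3 - 2


def _intergenic(rng: np.random.Generator, cfg: SynthConfig) -> str:
    L = rng.gamma(cfg.intergenic_shape,
                  cfg.intergenic_mean / cfg.intergenic_shape)
    return _random_dna(rng, max(cfg.intergenic_min, int(L)))


class _Item:
    """One placed element: an annotated gene or an unannotated relic.
    ``group`` ties the members of one planted structure together so they can
    be laid out with the short spacing of a tandem-duplication unit."""
    __slots__ = ("dna", "strand", "annotate", "meta", "intron", "group")

    def __init__(self, dna, strand, annotate, meta, intron=False, group=None):
        self.dna, self.strand = dna, strand
        self.annotate, self.meta, self.intron = annotate, meta, intron
        self.group = group


def _build_groups(cfg: SynthConfig, rng: np.random.Generator):
    """Materialise array / pair / dispersed plans into item groups plus
    pending truth records keyed by placement."""
    groups = []     # list of (kind, [items], truth_payload)
    for ai, plan in enumerate(cfg.arrays):
        fam = f"FAM{ai + 1:02d}"
        founder = random_gene(rng, _gene_length_codons(rng, cfg))
        ms_span = None
        if plan.minisat is not None:
            founder, ms0, ms1 = insert_minisatellite(
                founder, plan.minisat[0], plan.minisat[1], rng)
            ms_span = (ms0, ms1)
        orientations = plan.orientations or ("+",) * plan.size
        items = []
        member_info = []
        for i in range(plan.size):
            copy = founder if plan.identity >= 100 or i == 0 else \
                mutate_copy(founder, plan.identity, rng)
            aa_id = protein_identity(_protein(copy), _protein(founder))
            items.append(_Item(copy, orientations[i], True,
                               ("member", fam, aa_id, dna_identity(copy, founder),
                                ms_span if plan.minisat else None), group=fam))
            member_info.append(copy)
            if i in plan.spacers:
                spacer = random_gene(rng, _gene_length_codons(rng, cfg))
                items.append(_Item(spacer, "+", True, ("spacer", fam),
                                   group=fam))
        if plan.relic is not None:
            src = member_info[0] if plan.relic.position == "start" else member_info[-1]
            base = mutate_copy(src, plan.relic.identity, rng)
            relic = degrade_to_relic(base, plan.relic.n_disruptions,
                                     plan.relic.truncate_frac, rng)
            aa_id = protein_identity(_protein(base), _protein(src))
            payload = ("relic", fam, aa_id, dna_identity(relic, src, mode="HW"))
            item = _Item(relic, plan.relic.strand, False, payload, group=fam)
            if plan.relic.position == "start":
                items.insert(0, item)
            else:
                items.append(item)
        groups.append(("array", items, fam))

    for pi, pair in enumerate(cfg.minisat_pairs):
        tag = f"MSPAIR{pi + 1:02d}"
        items = []
        for _ in range(2):
            g = random_gene(rng, _gene_length_codons(rng, cfg))
            g, ms0, ms1 = insert_minisatellite(g, pair.unit_size,
                                               pair.copies, rng)
            items.append(_Item(g, "+", True,
                               ("mspair", tag, pair.unit_size, pair.copies,
                                (ms0, ms1)), group=tag))
        # both genes share the same repeat block
        shared = items[0].dna[items[0].meta[4][0]:items[0].meta[4][1]]
        d = items[1].dna
        s0, s1 = items[1].meta[4]
        items[1].dna = d[:s0] + shared + d[s1:]
        groups.append(("mspair", items, tag))

    for di, plan in enumerate(cfg.dispersed):
        fam = f"DISP{di + 1:02d}"
        founder = random_gene(rng, _gene_length_codons(rng, cfg))
        for i in range(plan.size):
            copy = founder if i == 0 else mutate_copy(founder, plan.identity, rng)
            aa_id = protein_identity(_protein(copy), _protein(founder))
            groups.append(("dispersed",
                           [_Item(copy, "+", True, ("dispersed", fam, aa_id))],
                           fam))
    return groups


MIN_GROUP_SEPARATION = 3  # background genes between planted structures


def generate_genome(cfg: SynthConfig,
                    out_dir: str | Path | None = None
                    ) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Build the genome and its truth ledger; optionally write FASTA +
    annotation (TSV and GFF3) + truth TSV to ``out_dir``.  Deterministic
    given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    groups = _build_groups(cfg, rng)
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    n_chrom = max(1, cfg.n_chromosomes)
    per_chrom_bg = [cfg.n_background // n_chrom] * n_chrom
    per_chrom_bg[0] += cfg.n_background % n_chrom
    chrom_groups: list[list] = [[] for _ in range(n_chrom)]
    for gi, grp in enumerate(groups):
        chrom_groups[gi % n_chrom].append(grp)

    chromosomes: dict[str, str] = {}
    features: dict[str, list[CdsFeature]] = {}
    truth = SyntheticTruth(seed=cfg.seed)
    pending_arrays: dict[str, PlantedArray] = {}

    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        n_bg = per_chrom_bg[ci]
        grps = chrom_groups[ci]
        gap = n_bg // (len(grps) + 1) if grps else n_bg
        if len(grps) >= 2 and gap < MIN_GROUP_SEPARATION:
            raise ValueError(
                f"infeasible packing: {len(grps)} planted structures need "
                f">= {MIN_GROUP_SEPARATION} background genes between them "
                f"but only {n_bg} background genes are available")
        if len(grps) == 1 and n_bg < 2:
            raise ValueError("infeasible packing: a planted structure needs "
                             "at least 2 background genes around it")
        insert_after = {(j + 1) * gap - 1: grps[j] for j in range(len(grps))}

        items: list[_Item] = []
        for b in range(n_bg):
            g = random_gene(rng, _gene_length_codons(rng, cfg))
            strand = "+" if rng.random() < 0.5 else "-"
            intron = (cfg.intron_fraction > 0 and
                      rng.random() < cfg.intron_fraction)
            items.append(_Item(g, strand, True, ("background",), intron))
            if b in insert_after:
                items.extend(insert_after[b][1])
        if n_bg == 0:
            for grp in grps:
                items.extend(grp[1])

        seq_parts: list[str] = []
        pos = 0
        feats: list[CdsFeature] = []
        gene_idx = 0
        placed: list[tuple[_Item, int, int, tuple]] = []
        prev_group = None
        for item in items:
            # members of one planted structure sit at the short spacing of a
            # tandem-duplication unit; unrelated neighbours get full
            # genome-wide intergenic gaps
            if item.meta and item.meta[0] == "relic":
                gapseq = _random_dna(rng, int(rng.integers(120, 260)))
            elif item.group is not None and item.group == prev_group:
                gapseq = _random_dna(rng, int(rng.integers(150, 450)))
            else:
                gapseq = _intergenic(rng, cfg)
            prev_group = item.group
            seq_parts.append(gapseq)
            pos += len(gapseq)
            dna = item.dna
            if item.strand == "-":
                dna = str(Seq(dna).reverse_complement())
            start = pos
            if item.annotate and item.intron:
                cut = 3 * ((len(dna) // 2) // 3)
                intron = ("GT" + _random_dna(rng, cfg.intron_length - 4) + "AG")
                dna = dna[:cut] + intron + dna[cut:]
                exons = ((start, start + cut),
                         (start + cut + len(intron), start + len(dna)))
            else:
                exons = ((start, start + len(dna)),)
            seq_parts.append(dna)
            pos += len(dna)
            end = pos
            if item.annotate:
                gene_idx += 1
                cid = f"{chrom}_g{gene_idx:04d}"
                feats.append(CdsFeature(cid, chrom, exons, item.strand))
            else:
                cid = None
            placed.append((item, start, end, (cid,)))
        seq_parts.append(_intergenic(rng, cfg))
        chromosomes[chrom] = "".join(seq_parts)
        features[chrom] = feats

        # truth records
        for item, start, end, (cid,) in placed:
            meta = item.meta
            kind = meta[0]
            if kind == "member":
                _, fam, aa_id, dna_id, ms_span = meta
                arr = pending_arrays.setdefault(
                    fam, PlantedArray(fam, chrom, []))
                arr.members.append(PlantedMember("cds", cid, chrom, start, end,
                                                 item.strand, aa_id, dna_id))
                if ms_span is not None:
                    truth.minisats.append(PlantedMinisat(
                        cid, cfg.arrays[int(fam[3:]) - 1].minisat[0],
                        cfg.arrays[int(fam[3:]) - 1].minisat[1],
                        ms_span[0], ms_span[1]))
            elif kind == "spacer":
                _, fam = meta
                arr = pending_arrays.setdefault(
                    fam, PlantedArray(fam, chrom, []))
                arr.members.append(PlantedMember("spacer", cid, chrom, start,
                                                 end, item.strand,
                                                 float("nan"), float("nan")))
            elif kind == "relic":
                _, fam, aa_id, dna_id = meta
                arr = pending_arrays.setdefault(
                    fam, PlantedArray(fam, chrom, []))
                arr.members.append(PlantedMember("relic", None, chrom, start,
                                                 end, item.strand, aa_id,
                                                 dna_id))
            elif kind == "mspair":
                _, tag, unit, copies, span = meta
                truth.minisats.append(PlantedMinisat(cid, unit, copies,
                                                     span[0], span[1]))
            elif kind == "dispersed":
                _, fam, aa_id = meta
                rec = next((f for f in truth.dispersed if f.family_id == fam),
                           None)
                if rec is None:
                    rec = PlantedFamily(fam, [], aa_id)
                    truth.dispersed.append(rec)
                rec.cds_ids.append(cid)

        pair_ids: dict[str, list[str]] = {}
        for item, start, end, (cid,) in placed:
            if item.meta[0] == "mspair":
                pair_ids.setdefault(item.meta[1], []).append(cid)
        for tag, ids in sorted(pair_ids.items()):
            truth.minisat_pair_ids.append(tuple(ids))

    for fam in sorted(pending_arrays):
        arr = pending_arrays[fam]
        arr.members.sort(key=lambda m: m.start)
        truth.arrays.append(arr)

    genome = AnnotatedGenome(chromosomes, features,
                             genetic_code=cfg.genetic_code)
    _assign_ranks(genome.features)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(genome, out / "genome.fa", out / "annotation.tsv")
        write_annotation_gff3(genome, out / "annotation.gff3")
        write_truth(truth, out / "truth.tsv")
    return genome, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Truth ledger TSV: one row per planted element (1-based coordinates,
    matching the annotation dialect)."""
    with open(path, "w") as fh:
        fh.write("#record\tfamily_id\tkind\tcds_id\tchromosome\tstart\tend\t"
                 "strand\taa_identity\tdna_identity\n")
        for arr in truth.arrays:
            for m in arr.members:
                fh.write(f"array\t{arr.family_id}\t{m.kind}\t{m.cds_id or '.'}\t"
                         f"{m.chromosome}\t{m.start + 1}\t{m.end}\t{m.strand}\t"
                         f"{m.aa_identity:.1f}\t{m.dna_identity:.1f}\n")
        for ms in truth.minisats:
            fh.write(f"minisat\t.\trepeat\t{ms.host_cds_id}\t.\t{ms.start + 1}\t"
                     f"{ms.end}\t+\t{float(ms.unit_size):.1f}\t"
                     f"{float(ms.copies):.1f}\n")
        for fam in truth.dispersed:
            fh.write(f"dispersed\t{fam.family_id}\tfamily\t"
                     f"{','.join(fam.cds_ids)}\t.\t0\t0\t+\t{fam.identity:.1f}\t"
                     f"0.0\n")


# ---------------------------------------------------------------------------
# canonical benchmark conditions
# ---------------------------------------------------------------------------

def recovery_benchmark_config(seed: int) -> SynthConfig:
    """The standard recovery-experiment genome: ~100 genes, planted arrays of
    sizes 2-5 at 80-100% amino-acid identity covering all four pair
    orientations, a one-spacer case, and both relic classes."""
    return SynthConfig(
        seed=seed,
        n_background=76,
        arrays=[
            ArrayPlan(size=2, identity=95),
            ArrayPlan(size=3, identity=88, orientations=("-", "-", "-")),
            ArrayPlan(size=2, identity=82, orientations=("+", "-")),
            ArrayPlan(size=2, identity=90, orientations=("-", "+")),
            ArrayPlan(size=4, identity=85),
            ArrayPlan(size=5, identity=92),
            ArrayPlan(size=3, identity=90, spacers=(0,)),
            ArrayPlan(size=2, identity=100),
            ArrayPlan(size=2, identity=88, relic=RelicPlan(position="end")),
            ArrayPlan(size=1, identity=100, relic=RelicPlan(position="end")),
        ],
    )
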