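"""Translated local alignment of a protein query against a DNA window.

The engine mimics a TBLASTN search: the window is translated in all six
frames, each frame is aligned to the query by full Smith-Waterman with affine
gaps (no seeding heuristics -- windows are at most a few tens of kb), and
multiple high-scoring segment pairs (HSPs) per frame are recovered by
recursively splitting the subject around each reported alignment.

Raw scores are converted to bit scores with fixed gapped Karlin-Altschul
parameters for BLOSUM62 / gap open 11 / gap extend 1 (lambda = 0.267,
K = 0.041); E-values use the uncorrected search space m*n = query length (aa)
x window length (bp).

Stop codons ('*') and ambiguous or masked residues ('X') score ``stop_score``
(default -4, the matrix minimum) against everything, including themselves.
Alignments can therefore extend across the stop codons and frameshift scars
of gene relics, while hard-masked (N -> X) regions can never raise a score.
"""

from __future__ import annotations

import functools
import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

log = logging.getLogger("tandemscan")

PLUS = "+"
MINUS = "-"

LN2 = math.log(2.0)


@dataclass(frozen=True)
class AlignParams:
    """Scoring context of the translated search.

    ``lam`` / ``k`` are the gapped Karlin-Altschul parameters matching the
    matrix and gap penalties; they are fixed, not estimated per genome.
    ``min_raw_score`` is a noise floor below which alignments are never
    reported regardless of E-value (for realistic window sizes the E-value
    cutoff is the stricter of the two).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    evalue_max: float = 1.0
    stop_score: int = -4
    min_raw_score: int = 10
    engine: str = "internal"  # "internal" or "tblastn"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if not 0 < self.k < 1:
            raise ValueError("K must be in (0, 1)")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")


@dataclass(frozen=True)
class Hsp:
    """One local alignment between the protein query and a window frame.

    Query coordinates are amino-acid offsets in the protein; subject
    coordinates are base-pair offsets in the window (both half-open, always
    on the window's plus strand regardless of HSP strand).
    """

    query_start: int
    query_end: int
    sbj_start: int
    sbj_end: int
    strand: str
    frame: int
    raw_score: float
    bit_score: float
    evalue: float

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start


def bit_score(raw_score: float, params: AlignParams) -> float:
    """Karlin-Altschul normalised score: (lambda*S - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.k)) / LN2


def evalue(raw_score: float, m: int, n: int, params: AlignParams) -> float:
    """E = K * m * n * exp(-lambda * S), no finite-size edge correction."""
    return params.k * m * n * math.exp(-params.lam * raw_score)


def min_significant_raw(m: int, n: int, params: AlignParams) -> float:
    """Smallest raw score whose E-value passes ``params.evalue_max``."""
    if m <= 0 or n <= 0:
        return math.inf
    s = math.log(params.k * m * n / params.evalue_max) / params.lam
    return max(float(params.min_raw_score), s)


@functools.lru_cache(maxsize=8)
def _matrix(name: str, stop_score: int):
    mat = substitution_matrices.load(name)
    alphabet = mat.alphabet
    mat = mat.copy()
    for ch in "*X":
        if ch not in alphabet:
            continue
        for other in alphabet:
            mat[ch, other] = stop_score
            mat[other, ch] = stop_score
    return mat


@functools.lru_cache(maxsize=8)
def _aligner(name: str, gap_open: int, gap_extend: int, stop_score: int):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(name, stop_score)
    # BLAST convention: a gap of length g costs open + g * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def get_aligner(params: AlignParams):
    return _aligner(params.matrix, params.gap_open, params.gap_extend,
                    params.stop_score)


def _sanitize(protein: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in protein.upper())


def _six_frames(dna: str, genetic_code: int) -> list[tuple[str, int, str]]:
    """(strand, frame, frame protein) for all six reading frames."""
    out = []
    rc = str(Seq(dna).reverse_complement())
    for strand, seq in ((PLUS, dna), (MINUS, rc)):
        for f in (0, 1, 2):
            ncod = (len(seq) - f) // 3
            if ncod < 1:
                continue
            sub = seq[f:f + 3 * ncod]
            prot = str(Seq(sub).translate(table=genetic_code))
            out.append((strand, f, prot))
    return out


def _aligned_spans(alignment) -> tuple[int, int, int, int]:
    blocks_t, blocks_q = alignment.aligned
    return (int(blocks_t[0][0]), int(blocks_t[-1][1]),
            int(blocks_q[0][0]), int(blocks_q[-1][1]))


def _frame_hsps(aligner, query: str, frame_prot: str, smin: float,
                collect: list[tuple[int, int, int, int, float]]) -> None:
    """Recursively harvest non-overlapping (on the subject) local alignments
    scoring at least ``smin``; appends (q0, q1, s0, s1, raw) in frame-protein
    amino-acid coordinates."""

    def rec(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        sub = frame_prot[lo:hi]
        raw = aligner.score(query, sub)
        if raw < smin:
            return
        aln = aligner.align(query, sub)[0]
        q0, q1, s0, s1 = _aligned_spans(aln)
        collect.append((q0, q1, lo + s0, lo + s1, float(raw)))
        if s0 > 0:
            rec(lo, lo + s0)
        if lo + s1 < hi:
            rec(lo + s1, hi)

    rec(0, len(frame_prot))


def search_window(protein: str, dna_window: str, params: AlignParams,
                  genetic_code: int = 1) -> list[Hsp]:
    """Six-frame translated search of ``protein`` against ``dna_window``.

    Returns HSPs with E-value <= ``params.evalue_max`` sorted by descending
    bit score.  Subject coordinates are window base-pair offsets.  Empty or
    degenerate (e.g. all-N) windows yield an empty list.
    """
    if not protein or len(dna_window) < 3:
        return []
    dna_window = dna_window.upper()
    aligner = get_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    query = _sanitize(protein, alphabet)
    m, n = len(query), len(dna_window)
    smin = min_significant_raw(m, n, params)
    if not math.isfinite(smin):
        return []

    hsps: list[Hsp] = []
    for strand, frame, frame_prot in _six_frames(dna_window, genetic_code):
        frame_prot = _sanitize(frame_prot, alphabet)
        found: list[tuple[int, int, int, int, float]] = []
        _frame_hsps(aligner, query, frame_prot, smin, found)
        for q0, q1, s0, s1, raw in found:
            if strand == PLUS:
                b0, b1 = frame + 3 * s0, frame + 3 * s1
            else:
                b0, b1 = n - (frame + 3 * s1), n - (frame + 3 * s0)
            hsps.append(Hsp(q0, q1, b0, b1, strand, frame, raw,
                            bit_score(raw, params), evalue(raw, m, n, params)))
    hsps = [h for h in hsps if h.evalue <= params.evalue_max]
    hsps.sort(key=lambda h: (-h.bit_score, h.strand, h.frame, h.sbj_start))
    return hsps


# ---------------------------------------------------------------------------
# TB aggregation
# ---------------------------------------------------------------------------

def _query_overlap_fraction(a: Hsp, b: Hsp) -> float:
    ov = min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
    if ov <= 0:
        return 0.0
    return ov / min(a.query_length, b.query_length)


def aggregate_tb(hsps: list[Hsp], strand: str,
                 max_overlap: float = 0.20) -> float:
    """Total TB score (bits) for one strand of one window search.

    HSPs of the given strand are taken greedily in descending bit-score
    order; a candidate is kept iff its query-span overlap with every kept HSP
    is at most ``max_overlap`` of the shorter of the two spans (HSPs
    overlapping by *more* than 20% are discarded).  Returns 0 for no HSPs.
    """
    kept: list[Hsp] = []
    pool = sorted((h for h in hsps if h.strand == strand),
                  key=lambda h: (-h.bit_score, h.sbj_start, h.query_start))
    eps = 1e-9
    for h in pool:
        if all(_query_overlap_fraction(h, k) <= max_overlap + eps for k in kept):
            kept.append(h)
    return sum(h.bit_score for h in kept)


# ---------------------------------------------------------------------------
# optional external TBLASTN engine
# ---------------------------------------------------------------------------

def search_window_tblastn(protein: str, dna_window: str, params: AlignParams,
                          genetic_code: int = 1) -> list[Hsp]:
    """Same contract as :func:`search_window`, delegated to the NCBI
    ``tblastn`` binary (fidelity mode; bit scores and E-values are then
    BLAST's own).  Low-complexity filtering and composition-based statistics
    are disabled to match the internal engine's scoring model."""
    if not protein or len(dna_window) < 3:
        return []
    if shutil.which("tblastn") is None:
        raise RuntimeError("tblastn binary not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qf, sf = Path(tmp, "q.fa"), Path(tmp, "s.fa")
        qf.write_text(f">q\n{protein}\n")
        sf.write_text(f">s\n{dna_window}\n")
        fmt = "6 qstart qend sstart send sframe bitscore evalue score"
        res = subprocess.run(
            ["tblastn", "-query", str(qf), "-subject", str(sf),
             "-evalue", str(params.evalue_max), "-outfmt", fmt,
             "-seg", "no", "-comp_based_stats", "0",
             "-db_gencode", str(genetic_code)],
            capture_output=True, text=True, check=True)
    hsps = []
    for line in res.stdout.splitlines():
        qs, qe, ss, se, sframe, bits, ev, raw = line.split("\t")
        qs, qe, ss, se, sframe = int(qs), int(qe), int(ss), int(se), int(sframe)
        if sframe > 0:
            strand, b0, b1 = PLUS, ss - 1, se
        else:
            strand, b0, b1 = MINUS, se - 1, ss
        hsps.append(Hsp(qs - 1, qe, b0, b1, strand, abs(sframe) - 1,
                        float(raw), float(bits), float(ev)))
    hsps.sort(key=lambda h: (-h.bit_score, h.strand, h.frame, h.sbj_start))
    return hsps


def run_search(protein: str, dna_window: str, params: AlignParams,
               genetic_code: int = 1) -> list[Hsp]:
    """Dispatch on ``params.engine``."""
    if params.engine == "tblastn":
        return search_window_tblastn(protein, dna_window, params, genetic_code)
    return search_window(protein, dna_window, params, genetic_code)
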