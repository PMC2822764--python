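"""Tandem-repeat (minisatellite) detection and dotplot diagonals.

Minisatellites inside the coding sequence of tandem gene pairs can fake the
inter-gene similarity that the FTB statistic measures, so every CDS in a
detected array is screened for them.  The two-stage scan mirrors the classic
EMBOSS pair: a fast autocorrelation pass proposes candidate unit sizes
(equicktandem-style), then an exact consensus scorer evaluates them
(etandem-style).  Both are reimplementations of the scoring definitions
below; equivalence with EMBOSS output is not claimed.  Repeat units are
matched without gaps (whole-unit copies, substitutions only).

The dotplot follows the DNA Strider convention: a dot at (i, j) iff the
length-``window`` words starting there share at least ``stringency``
identical letters; dots on a common diagonal are merged into runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("tandemscan")

QUICK_MAX_UNIT = 600
QUICK_THRESHOLD = 20
ETANDEM_MIN_UNIT = 10
ETANDEM_MAX_UNIT = 300
DNA_DOT_WINDOW = 23
DNA_DOT_STRINGENCY = 15
PROTEIN_DOT_STRINGENCY = 5


@dataclass(frozen=True)
class TandemRepeat:
    """A tandem repeat block: ``copy_count`` whole copies of a ``unit_size``
    bp unit spanning ``[start, end)``, scored as matches minus mismatches
    against the column-majority consensus."""

    unit_size: int
    copy_count: int
    start: int
    end: int
    consensus: str
    score: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DotplotHit:
    """Maximal run of dots on one diagonal.  ``a_start`` / ``b_start`` are
    the word-start coordinates of the first dot; the covered sequence spans
    are ``length + window - 1`` letters long."""

    diagonal: int
    a_start: int
    b_start: int
    length: int
    window: int

    @property
    def a_end(self) -> int:
        """End (exclusive) of the covered span on sequence a."""
        return self.a_start + self.length + self.window - 1

    @property
    def b_end(self) -> int:
        return self.b_start + self.length + self.window - 1


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _longest_true_run(mask: np.ndarray) -> int:
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def quick_tandem_scan(dna: str, max_unit: int = QUICK_MAX_UNIT,
                      threshold: int = QUICK_THRESHOLD,
                      min_unit: int = 1) -> list[tuple[int, int]]:
    """Fast candidate-unit scan by autocorrelation.

    For each unit size u the sequence is compared with itself at lag u; the
    score of a unit is the length of the longest run of consecutive matches.
    Units scoring >= ``threshold`` are reported best-first; a unit that is a
    multiple of an already-reported unit is dropped as redundant.
    """
    arr = _codes(dna)
    hits: list[tuple[int, int]] = []
    for u in range(max(1, min_unit), min(max_unit, len(arr) // 2) + 1):
        score = _longest_true_run(arr[:-u] == arr[u:])
        if score >= threshold:
            hits.append((u, score))
    hits.sort(key=lambda t: (-t[1], t[0]))
    kept: list[tuple[int, int]] = []
    for u, s in hits:
        if any(u % ku == 0 for ku, _ in kept):
            continue
        kept.append((u, s))
    return kept


def exact_tandem(dna: str, min_unit: int = ETANDEM_MIN_UNIT,
                 max_unit: int = ETANDEM_MAX_UNIT,
                 candidates: list[int] | None = None) -> TandemRepeat | None:
    """Best tandem repeat under consensus scoring, or None.

    For every unit size u (``candidates`` if given, else the full range),
    every phase and every contiguous block of >= 2 whole copies, the block is
    scored as (positions matching the column-majority consensus) minus
    (positions mismatching it).  The maximal-scoring positive block wins;
    ties break toward smaller unit, then leftmost span.
    """
    n = len(dna)
    arr = _codes(dna)
    # map bytes to dense codes 0..k-1
    letters, dense = np.unique(arr, return_inverse=True)
    k = len(letters)
    units = sorted(set(candidates)) if candidates else \
        range(min_unit, min(max_unit, n // 2) + 1)
    best: tuple[int, int, int, int, int] | None = None  # (-score, u, start, rows, phase)
    for u in units:
        if u < min_unit or u > max_unit or 2 * u > n:
            continue
        for phase in range(u):
            rows = (n - phase) // u
            if rows < 2:
                continue
            block = dense[phase:phase + rows * u].reshape(rows, u)
            onehot = np.zeros((rows, k, u), dtype=np.int32)
            r_idx = np.arange(rows)[:, None]
            c_idx = np.arange(u)[None, :]
            onehot[r_idx, block, c_idx] = 1
            cum = onehot.cumsum(axis=0)
            for a in range(rows - 1):
                counts = cum[a + 1:] - (cum[a - 1 + 1] - onehot[a])
                matches = counts.max(axis=1).sum(axis=1)
                kcopies = np.arange(2, rows - a + 1)
                scores = 2 * matches - kcopies * u
                j = int(scores.argmax())
                sc = int(scores[j])
                cand = (-sc, u, phase + a * u, int(kcopies[j]), phase)
                if sc > 0 and (best is None or cand < best):
                    best = cand
    if best is None:
        return None
    neg_score, u, start, copies, _ = best
    block = dense[start:start + copies * u].reshape(copies, u)
    consensus_chars = []
    for col in range(u):
        counts = np.bincount(block[:, col], minlength=k)
        top = counts.max()
        # deterministic tie-break: lexicographically smallest letter
        ch = min(letters[np.flatnonzero(counts == top)])
        consensus_chars.append(chr(ch))
    return TandemRepeat(unit_size=u, copy_count=copies, start=start,
                        end=start + copies * u,
                        consensus="".join(consensus_chars), score=-neg_score)


def find_minisatellite(dna: str, min_unit: int = ETANDEM_MIN_UNIT,
                       max_unit: int = ETANDEM_MAX_UNIT,
                       quick_threshold: int = QUICK_THRESHOLD) -> TandemRepeat | None:
    """Two-stage scan: quick candidate units, then exact consensus scoring."""
    cands = [u for u, _ in quick_tandem_scan(dna, QUICK_MAX_UNIT,
                                             quick_threshold)]
    cands = [u for u in cands if min_unit <= u <= max_unit]
    if not cands:
        return None
    return exact_tandem(dna, min_unit, max_unit, candidates=cands)


def dotplot(seq_a: str, seq_b: str, window: int = DNA_DOT_WINDOW,
            stringency: int = DNA_DOT_STRINGENCY,
            alphabet: str = "dna") -> list[DotplotHit]:
    """All maximal diagonal runs of dots between two sequences.

    A dot sits at word-start coordinates (i, j) iff
    ``sum(seq_a[i + t] == seq_b[j + t] for t in range(window)) >= stringency``.
    ``alphabet`` is documentation only (DNA mode 15/23, protein mode 5/23).
    """
    a, b = _codes(seq_a), _codes(seq_b)
    la, lb = len(a), len(b)
    if la < window or lb < window:
        return []
    hits: list[DotplotHit] = []
    # diagonal d: j = i + d
    for d in range(-(la - window), lb - window + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        L = min(la - i0, lb - j0)
        if L < window:
            continue
        eq = (a[i0:i0 + L] == b[j0:j0 + L]).astype(np.int32)
        c = np.concatenate(([0], np.cumsum(eq)))
        sums = c[window:] - c[:-window]          # identity count per word start
        dots = sums >= stringency
        if not dots.any():
            continue
        padded = np.concatenate(([False], dots, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            hits.append(DotplotHit(diagonal=d, a_start=i0 + int(s),
                                   b_start=j0 + int(s), length=int(e - s),
                                   window=window))
    hits.sort(key=lambda h: (-h.length, h.diagonal, h.a_start))
    return hits


# ---------------------------------------------------------------------------
# minisatellite screening of assembled arrays
# ---------------------------------------------------------------------------

@dataclass
class MinisatReport:
    """Repeat screen of one TGA: confirmed repeats per member CDS, whether
    the array is flagged suspicious, and whether masked re-scoring rejected
    it as repeat-driven."""
    tga_id: str
    repeats: list = field(default_factory=list)  # (cds_id, TandemRepeat)
    flagged: bool = False
    rejected: bool = False


def flag_minisatellite_tgas(tgas, genome, score_df, params=None,
                            threshold: float = 10.0,
                            factor: float = 3.0, min_len: int = 1500,
                            min_unit: int = ETANDEM_MIN_UNIT,
                            max_unit: int = ETANDEM_MAX_UNIT,
                            quick_threshold: int = QUICK_THRESHOLD
                            ) -> dict[str, MinisatReport]:
    """Screen every member CDS of every TGA for internal tandem repeats.

    A TGA with any confirmed repeat is flagged suspicious.  It is rejected
    only if, with all repeat spans hard-masked, no adjacent homologous pair
    retains facing FTB scores at or above the threshold -- i.e. the apparent
    inter-gene similarity was due to the shared repeat, not to gene homology.
    Masked FTB scores are normalised by the original (unmasked) self-scores,
    so masking can only lower them.
    """
    from .align import AlignParams, aggregate_tb, run_search, PLUS, MINUS
    from .genome_io import (DOWNSTREAM, UPSTREAM, flanking_window,
                            mask_intervals, spliced_dna, spliced_to_genomic,
                            translate_cds)
    from .scoring import FtbScoreSet, TbScoreSet, apply_filter, compute_ftb
    from .extraction import is_significant

    params = params or AlignParams()
    self_scores = dict(zip(score_df["cds_id"], score_df["tb_self"]))
    reports: dict[str, MinisatReport] = {}

    for tga in tgas:
        rep = MinisatReport(tga_id=tga.id)
        mask_ivs = []
        for m in tga.cds_members():
            seq = spliced_dna(genome, m.cds)
            hit = find_minisatellite(seq, min_unit, max_unit, quick_threshold)
            if hit is not None:
                rep.repeats.append((m.cds.id, hit))
                mask_ivs.extend(spliced_to_genomic(m.cds, hit.start, hit.end))
        rep.flagged = bool(rep.repeats)
        if rep.flagged:
            masked = mask_intervals(genome, mask_ivs)

            def masked_side_scores(cds, side):
                window = flanking_window(masked, cds, side, factor, min_len)
                prot = translate_cds(masked, cds)
                hsps = run_search(prot, masked.sequence(window), params,
                                  genetic_code=masked.genetic_code)
                self_tb = float(self_scores[cds.id])
                tb_p = aggregate_tb(hsps, PLUS)
                tb_m = aggregate_tb(hsps, MINUS)
                x = 100.0 * tb_p / self_tb
                y = 100.0 * tb_m / self_tb
                key = "up" if side == UPSTREAM else "down"
                fs = FtbScoreSet(**{
                    "f_up_plus": x - y if key == "up" else 0.0,
                    "f_up_minus": y - x if key == "up" else 0.0,
                    "f_down_plus": x - y if key == "down" else 0.0,
                    "f_down_minus": y - x if key == "down" else 0.0})
                return apply_filter(fs, self_tb)

            members = tga.homologous_members()
            retained = False
            for a, b in zip(members, members[1:]):
                if a.kind != "cds" or b.kind != "cds":
                    retained = True  # relic pairs are not re-screened here
                    continue
                fa = masked_side_scores(a.cds, DOWNSTREAM)
                fb = masked_side_scores(b.cds, UPSTREAM)
                if (is_significant(fa, "down", threshold) is not None and
                        is_significant(fb, "up", threshold) is not None):
                    retained = True
                    break
            rep.rejected = not retained
        reports[tga.id] = rep
    return reports
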