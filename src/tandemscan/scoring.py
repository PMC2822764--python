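"""Per-CDS TB/FTB score table.

For every CDS the protein is searched against both strands of its two
flanking windows, giving four TB scores (bits).  Each is normalised by the
TB self-score (protein vs its own spliced coding sequence) to a
percent-of-self value, and the two strands of a side are differenced:

    X = 100 * TB(plus) / TB(self),  Y = 100 * TB(minus) / TB(self)
    FTB(plus) = X - Y,              FTB(minus) = Y - X

so background similarity that hits both strands of a window cancels.  A
small-protein filter then shrinks weak scores of weakly self-scoring CDSs:
if TB(self) < 250 and 0 < FTB < 50, FTB -= (250 - TB(self)) / 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .align import AlignParams, aggregate_tb, run_search, PLUS, MINUS
from .genome_io import (AnnotatedGenome, CdsFeature, AnnotationError,
                        DEFAULT_MIN_WINDOW, DEFAULT_WINDOW_FACTOR,
                        DOWNSTREAM, UPSTREAM, flanking_window, spliced_dna,
                        translate_cds)

log = logging.getLogger("tandemscan")

#: small-protein filter constants (self-score ceiling, score ceiling, slope)
FILTER_SELF_MAX = 250.0
FILTER_SCORE_MAX = 50.0
FILTER_SLOPE = 4.0

SCORE_COLUMNS = ["cds_id", "chromosome", "rank", "strand", "tb_self",
                 "f_up_plus", "f_up_minus", "f_down_plus", "f_down_minus",
                 "flags"]


class DegenerateAnnotationError(AnnotationError):
    """A CDS whose protein does not even align to its own coding sequence."""


@dataclass(frozen=True)
class TbScoreSet:
    """Raw TB scores (bits) of one CDS: four window scores plus self-score."""
    tb_up_plus: float
    tb_up_minus: float
    tb_down_plus: float
    tb_down_minus: float
    tb_self: float


@dataclass
class FtbScoreSet:
    """The four FTB scores of one CDS, in percent-of-self units.

    Before filtering each side satisfies f_plus == -f_minus exactly; the
    filter (see :func:`apply_filter`) can break the antisymmetry for the
    positive member of a pair, recorded per score in ``filtered_flags``.
    """
    f_up_plus: float
    f_up_minus: float
    f_down_plus: float
    f_down_minus: float
    filtered_flags: tuple[str, ...] = ()

    FIELDS = ("f_up_plus", "f_up_minus", "f_down_plus", "f_down_minus")


def compute_self_score(genome: AnnotatedGenome, cds: CdsFeature,
                       params: AlignParams) -> float:
    """TB-style aggregate of the CDS protein against its own spliced coding
    sequence (plus strand of the coding orientation)."""
    protein = translate_cds(genome, cds)
    hsps = run_search(protein, spliced_dna(genome, cds), params,
                      genetic_code=genome.genetic_code)
    tb = aggregate_tb(hsps, PLUS)
    if tb <= 0:
        raise DegenerateAnnotationError(
            f"{cds.id}: non-positive TB self-score ({tb})")
    return tb


def compute_tb_scores(genome: AnnotatedGenome, cds: CdsFeature,
                      params: AlignParams,
                      factor: float = DEFAULT_WINDOW_FACTOR,
                      min_len: int = DEFAULT_MIN_WINDOW) -> TbScoreSet:
    """All five TB scores of one CDS."""
    protein = translate_cds(genome, cds)
    scores = {}
    for side, key in ((UPSTREAM, "up"), (DOWNSTREAM, "down")):
        window = flanking_window(genome, cds, side, factor, min_len)
        hsps = run_search(protein, genome.sequence(window), params,
                          genetic_code=genome.genetic_code)
        scores[f"tb_{key}_plus"] = aggregate_tb(hsps, PLUS)
        scores[f"tb_{key}_minus"] = aggregate_tb(hsps, MINUS)
    return TbScoreSet(tb_self=compute_self_score(genome, cds, params), **scores)


def compute_ftb(tb: TbScoreSet) -> FtbScoreSet:
    """Strand-differenced percent-of-self scores (antisymmetric per side)."""
    if tb.tb_self <= 0:
        raise DegenerateAnnotationError("TB self-score must be positive")
    x_up = 100.0 * tb.tb_up_plus / tb.tb_self
    y_up = 100.0 * tb.tb_up_minus / tb.tb_self
    x_down = 100.0 * tb.tb_down_plus / tb.tb_self
    y_down = 100.0 * tb.tb_down_minus / tb.tb_self
    return FtbScoreSet(x_up - y_up, y_up - x_up,
                       x_down - y_down, y_down - x_down)


def apply_filter(ftb: FtbScoreSet, tb_self: float) -> FtbScoreSet:
    """Small-protein filter, applied independently to each of the four
    scores meeting the condition (self < 250 and 0 < score < 50)."""
    if tb_self >= FILTER_SELF_MAX:
        return replace(ftb, filtered_flags=())
    penalty = (FILTER_SELF_MAX - tb_self) / FILTER_SLOPE
    values = {}
    flagged = []
    for name in FtbScoreSet.FIELDS:
        v = getattr(ftb, name)
        if 0 < v < FILTER_SCORE_MAX:
            values[name] = v - penalty
            flagged.append(name)
        else:
            values[name] = v
    return FtbScoreSet(filtered_flags=tuple(flagged), **values)


def score_cds(genome: AnnotatedGenome, cds: CdsFeature, params: AlignParams,
              factor: float = DEFAULT_WINDOW_FACTOR,
              min_len: int = DEFAULT_MIN_WINDOW,
              filter_small: bool = True) -> tuple[TbScoreSet, FtbScoreSet]:
    tb = compute_tb_scores(genome, cds, params, factor, min_len)
    ftb = compute_ftb(tb)
    if filter_small:
        ftb = apply_filter(ftb, tb.tb_self)
    return tb, ftb


def score_genome(genome: AnnotatedGenome, params: AlignParams | None = None,
                 factor: float = DEFAULT_WINDOW_FACTOR,
                 min_len: int = DEFAULT_MIN_WINDOW,
                 filter_small: bool = True) -> pd.DataFrame:
    """Score every CDS of a genome; one row per CDS in (chromosome, rank)
    order.  Untranslatable or degenerate CDSs get null scores and a log line.
    Deterministic given inputs and parameters."""
    params = params or AlignParams()
    rows = []
    for cds in genome.all_features():
        row = {"cds_id": cds.id, "chromosome": cds.chromosome,
               "rank": cds.rank, "strand": cds.strand}
        try:
            tb, ftb = score_cds(genome, cds, params, factor, min_len,
                                filter_small)
        except AnnotationError as exc:
            log.warning("skipping %s: %s", cds.id, exc)
            row.update(tb_self=float("nan"),
                       **{k: float("nan") for k in FtbScoreSet.FIELDS},
                       flags="untranslatable")
        else:
            row.update(tb_self=tb.tb_self,
                       **{k: getattr(ftb, k) for k in FtbScoreSet.FIELDS},
                       flags=";".join(ftb.filtered_flags))
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    """Persist the score table as TSV with fixed 2-decimal float formatting
    (identical inputs and config give byte-identical files)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"flags": "string"})
    df["flags"] = df["flags"].fillna("")
    return df
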