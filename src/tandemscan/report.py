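"""Summary statistics, protein identities and the parameter-sweep harness."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignParams, evalue as _evalue, get_aligner
from .extraction import Tga, extract_tgas
from .genome_io import AnnotatedGenome, translate_cds
from .scoring import score_genome

log = logging.getLogger("tandemscan")


@dataclass
class TgaSummary:
    n_cds_total: int
    n_cds_in_tgas: int
    pct_cds_in_tgas: float
    n_tgas: int
    size_class_counts: dict[str, int] = field(default_factory=dict)
    orientation_counts: dict[str, int] = field(default_factory=dict)
    n_tgas_with_relic: int = 0
    frac_tgas_with_relic: float = 0.0


def summarize(tgas: list[Tga], genome: AnnotatedGenome) -> TgaSummary:
    """Per-genome TGA census: counts by size class (2CDS, 3CDS, ...,
    1CDS-relic, nCDSs-relic) and by orientation class, plus the fraction of
    arrays containing a gene relic.  Spacer members are not counted as CDSs
    in arrays."""
    n_total = genome.n_cds()
    n_in = sum(t.n_cds for t in tgas)
    size_counts: dict[str, int] = {}
    orient_counts: dict[str, int] = {}
    n_relic = 0
    for t in tgas:
        key = t.size_class if t.size_class != "nCDS" else f"{t.n_cds}CDS"
        size_counts[key] = size_counts.get(key, 0) + 1
        orient_counts[t.orientation_class] = \
            orient_counts.get(t.orientation_class, 0) + 1
        if any(m.kind == "relic" for m in t.members) or "relic" in t.size_class:
            n_relic += 1
    n_tgas = len(tgas)
    return TgaSummary(
        n_cds_total=n_total, n_cds_in_tgas=n_in,
        pct_cds_in_tgas=(100.0 * n_in / n_total) if n_total else 0.0,
        n_tgas=n_tgas, size_class_counts=size_counts,
        orientation_counts=orient_counts, n_tgas_with_relic=n_relic,
        frac_tgas_with_relic=(n_relic / n_tgas) if n_tgas else 0.0)


def write_summary(summary: TgaSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"n_cds_total\t{summary.n_cds_total}\n")
        fh.write(f"n_cds_in_tgas\t{summary.n_cds_in_tgas}\n")
        fh.write(f"pct_cds_in_tgas\t{summary.pct_cds_in_tgas:.1f}\n")
        fh.write(f"n_tgas\t{summary.n_tgas}\n")
        for k in sorted(summary.size_class_counts):
            fh.write(f"size_class:{k}\t{summary.size_class_counts[k]}\n")
        for k in sorted(summary.orientation_counts):
            fh.write(f"orientation:{k}\t{summary.orientation_counts[k]}\n")
        fh.write(f"n_tgas_with_relic\t{summary.n_tgas_with_relic}\n")
        fh.write(f"frac_tgas_with_relic\t{summary.frac_tgas_with_relic:.3f}\n")


def expected_opposite_in_large(p_opposite: float, p_ge3: float) -> float:
    """Expected frequency of mixed arrays under independence: the product of
    the opposite-pair frequency and the frequency of arrays with >= 3
    copies, rounded to 3 decimals as reported."""
    for v in (p_opposite, p_ge3):
        if not 0.0 <= v <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    return round(p_opposite * p_ge3, 3)


def pair_identity(protein_a: str, protein_b: str,
                  params: AlignParams | None = None) -> float | None:
    """Percent identity of the best local alignment of two proteins
    (no low-complexity masking): 100 * identities / alignment length,
    gap columns included.  Returns None when no alignment reaches the
    E-value cutoff."""
    params = params or AlignParams()
    if not protein_a or not protein_b:
        return None
    aligner = get_aligner(params)
    raw = aligner.score(protein_a, protein_b)
    if raw <= 0 or _evalue(raw, len(protein_a), len(protein_b),
                           params) > params.evalue_max:
        return None
    counts = aligner.align(protein_a, protein_b)[0].counts()
    length = counts.identities + counts.mismatches + counts.internal_gaps
    if length == 0:
        return None
    return 100.0 * counts.identities / length


def tga_pair_identities(tgas: list[Tga], genome: AnnotatedGenome,
                        params: AlignParams | None = None) -> list[float]:
    """Identities of all within-array CDS pairs (relics, having no protein,
    are skipped)."""
    out = []
    for t in tgas:
        prots = [translate_cds(genome, m.cds) for m in t.cds_members()]
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                ident = pair_identity(prots[i], prots[j], params)
                if ident is not None:
                    out.append(ident)
    return out


def family_pair_identities(families: list[list[str]],
                           genome: AnnotatedGenome, rng,
                           params: AlignParams | None = None) -> list[float]:
    """One randomly sampled pair per family (avoids biasing the identity
    distribution toward large families)."""
    out = []
    for ids in families:
        if len(ids) < 2:
            continue
        i, j = rng.choice(len(ids), size=2, replace=False)
        ident = pair_identity(translate_cds(genome, genome.feature(ids[i])),
                              translate_cds(genome, genome.feature(ids[j])),
                              params)
        if ident is not None:
            out.append(ident)
    return out


def sweep_parameters(genome: AnnotatedGenome,
                     factors=(2.0, 3.0), thresholds=(10.0, 15.0),
                     params: AlignParams | None = None,
                     min_len: int = 1500,
                     allow_spacer: bool = True) -> pd.DataFrame:
    """Full pipeline re-run per (window factor, FTB threshold) cell.

    Scoring depends only on the factor, so each factor is scored once and
    re-extracted per threshold.  Returns one row per cell with the TGA and
    tagged-CDS counts (before curation)."""
    params = params or AlignParams()
    rows = []
    for factor in factors:
        df = score_genome(genome, params, factor=factor, min_len=min_len)
        for thr in thresholds:
            res = extract_tgas(df, genome, threshold=thr,
                               allow_spacer=allow_spacer)
            rows.append({"factor": factor, "threshold": thr,
                         "n_tgas": len(res.tgas),
                         "n_tagged": len(res.tagged)})
    return pd.DataFrame(rows, columns=["factor", "threshold",
                                       "n_tgas", "n_tagged"])
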