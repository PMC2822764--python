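"""Recovery benchmark: run the full pipeline on synthetic genomes with
planted truth and measure how much of the truth is recovered.

Metrics per genome:

* exact-member array recovery -- a planted array with >= 2 CDS copies counts
  as recovered only if some detected TGA has exactly its CDS member set;
* orientation accuracy over exactly recovered all-CDS arrays;
* relic confirmation -- a planted relic counts as confirmed if curation
  attaches a relic member overlapping the true relic locus to a TGA that
  contains the host CDS;
* background false positives -- detected arrays none of whose members belong
  to any planted family;
* tagged-CDS and TGA counts at FTB thresholds 10 and 15 (same score table),
  for the threshold-monotonicity check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignParams
from .extraction import curate_tagged, extract_tgas
from .repeats import flag_minisatellite_tgas
from .scoring import score_genome
from .synthesis import (SynthConfig, SyntheticTruth, generate_genome,
                        recovery_benchmark_config)

log = logging.getLogger("tandemscan")

_ORIENT = {("+", "+"): "direct_sense", ("-", "-"): "direct_antisense",
           ("+", "-"): "opposite_convergent", ("-", "+"): "opposite_divergent"}


def expected_orientation(strands: list[str]) -> str:
    classes = {_ORIENT[(a, b)] for a, b in zip(strands, strands[1:])}
    return classes.pop() if len(classes) == 1 else "mixed"


@dataclass
class GenomeEvaluation:
    seed: int
    n_cds: int = 0
    arrays_total: int = 0
    arrays_exact: int = 0
    orientations_checked: int = 0
    orientations_correct: int = 0
    relics_total: int = 0
    relics_confirmed: int = 0
    false_positive_tgas: int = 0
    n_tgas_thr10: int = 0
    n_tgas_thr15: int = 0
    n_tagged_thr10: int = 0
    n_tagged_thr15: int = 0


def evaluate_genome(cfg: SynthConfig,
                    params: AlignParams | None = None,
                    threshold: float = 10.0,
                    alt_threshold: float = 15.0) -> GenomeEvaluation:
    """Generate one synthetic genome, run scoring -> extraction -> curation
    -> repeat screening, and compare the outcome with the planted truth."""
    params = params or AlignParams()
    genome, truth = generate_genome(cfg)
    ev = GenomeEvaluation(seed=cfg.seed, n_cds=genome.n_cds())

    scores = score_genome(genome, params)
    res = extract_tgas(scores, genome, threshold=threshold)
    cur = curate_tagged(res.tagged, scores, genome, res.tgas,
                        threshold=threshold)
    all_tgas = res.tgas + cur.new_tgas
    reports = flag_minisatellite_tgas(all_tgas, genome, scores, params,
                                      threshold=threshold)
    kept = [t for t in all_tgas if not reports[t.id].rejected]

    planted_ids = {cid for arr in truth.arrays for cid in arr.cds_ids()}
    planted_ids |= {m.cds_id for arr in truth.arrays for m in arr.members
                    if m.cds_id}
    for fam in truth.dispersed:
        planted_ids.update(fam.cds_ids)
    for pair in truth.minisat_pair_ids:
        planted_ids.update(pair)

    tga_sets = {t.id: frozenset(m.cds.id for m in t.cds_members())
                for t in kept}
    by_set = {s: t for t in kept for s in [tga_sets[t.id]]}

    for arr in truth.arrays:
        want = frozenset(arr.cds_ids())
        if len(want) >= 2:
            ev.arrays_total += 1
            hit = by_set.get(want)
            if hit is not None:
                ev.arrays_exact += 1
                if not arr.has_relic():
                    ev.orientations_checked += 1
                    strands = [m.strand for m in arr.members
                               if m.kind == "cds"]
                    if hit.orientation_class == expected_orientation(strands):
                        ev.orientations_correct += 1
        relic = next((m for m in arr.members if m.kind == "relic"), None)
        if relic is not None:
            ev.relics_total += 1
            host_ids = set(arr.cds_ids())
            for t in kept:
                members = {m.cds.id for m in t.cds_members()}
                if not members & host_ids:
                    continue
                for m in t.members:
                    if (m.kind == "relic" and
                            m.relic_interval.chromosome == relic.chromosome and
                            min(m.relic_interval.end, relic.end) >
                            max(m.relic_interval.start, relic.start)):
                        ev.relics_confirmed += 1
                        break
                else:
                    continue
                break

    for t in kept:
        members = {m.cds.id for m in t.cds_members()}
        if members and not members & planted_ids:
            ev.false_positive_tgas += 1

    ev.n_tgas_thr10 = len(res.tgas)
    ev.n_tagged_thr10 = len(res.tagged)
    alt = extract_tgas(scores, genome, threshold=alt_threshold)
    ev.n_tgas_thr15 = len(alt.tgas)
    ev.n_tagged_thr15 = len(alt.tagged)
    return ev


@dataclass
class ExperimentSummary:
    evaluations: list[GenomeEvaluation] = field(default_factory=list)

    @property
    def array_recovery_pct(self) -> float:
        tot = sum(e.arrays_total for e in self.evaluations)
        hit = sum(e.arrays_exact for e in self.evaluations)
        return 100.0 * hit / tot if tot else 0.0

    @property
    def orientation_accuracy_pct(self) -> float:
        tot = sum(e.orientations_checked for e in self.evaluations)
        hit = sum(e.orientations_correct for e in self.evaluations)
        return 100.0 * hit / tot if tot else 0.0

    @property
    def relic_confirmation_pct(self) -> float:
        tot = sum(e.relics_total for e in self.evaluations)
        hit = sum(e.relics_confirmed for e in self.evaluations)
        return 100.0 * hit / tot if tot else 0.0

    @property
    def total_false_positives(self) -> int:
        return sum(e.false_positive_tgas for e in self.evaluations)


def recovery_experiment(seeds: list[int],
                        params: AlignParams | None = None
                        ) -> ExperimentSummary:
    """Run the standard benchmark genome for each seed."""
    out = ExperimentSummary()
    for seed in seeds:
        out.evaluations.append(
            evaluate_genome(recovery_benchmark_config(seed), params))
        log.info("seed %d done", seed)
    return out
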