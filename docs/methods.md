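# Methods

## The vicinity-search model

The method treats tandem duplication as a *local* phenomenon: if a gene has
a tandem copy, that copy — intact or degenerated — lies within a few gene
lengths on the same chromosome. Each annotated CDS is therefore compared
only with its two flanking windows, never with the rest of the genome. This
makes relic detection possible (the search target is raw DNA, not the
protein complement) and keeps the cost linear in gene count.

Assumptions worth stating explicitly:

* the annotation is trusted — no gene prediction is attempted, and for loci
  with several isoforms only the first is used;
* the genome is compact. Windows of 3 × L<sub>CDS</sub> (≥ 1.5 kb) reach the
  neighbouring one or two genes in a yeast-like genome (≈1.4 kb genes, one
  gene per ≈2 kb). In genomes with long intergenic distances or long introns
  the same windows would cover nothing, and the method degrades;
* duplicated copies retain enough protein-level similarity to align; the
  practical floor is ≈30–40% amino-acid identity, far below the divergence
  of recently formed tandem pairs.

## Scoring

**Translated search.** The protein of each CDS is aligned to all six frames
of each flanking window by full Smith–Waterman with affine gaps (BLOSUM62,
gap open 11, extend 1). There is no seeding heuristic: at window sizes of a
few kb, exact DP is affordable and removes a whole class of sensitivity
artefacts. Additional HSPs per frame are harvested by recursively splitting
the subject around each reported alignment, so HSPs never overlap on the
subject. Raw scores S become bit scores via fixed gapped Karlin–Altschul
parameters (λ = 0.267, K = 0.041 — published values for this
matrix/penalty combination; they are not re-estimated per genome), and
E = K·m·n·exp(−λS) with m·n = query length (aa) × window length (bp),
uncorrected for edge effects. HSPs with E ≤ 1.0 are kept. A raw-score floor
(default 10) additionally suppresses the one- and two-residue "alignments"
that the uncorrected E-value formula admits on very small search spaces;
for realistic window sizes the E-value cutoff is the binding constraint and
the floor is inert.

**Stop codons and masked residues.** The matrix rows for `*` and `X` are
set uniformly to −4 (the matrix minimum), including their diagonals.
Alignments can therefore extend *across* the stop codons and frameshift
scars of a gene relic at a bounded cost — essential for relic detection —
while hard-masked (N→X) sequence can never raise any alignment score, which
makes masked re-scoring (below) conservative by construction.

**TB aggregation.** Per window and strand, HSPs are taken greedily in
descending bit-score order; a candidate is kept iff its query-span overlap
with every kept HSP is ≤ 20% of the shorter span (strictly more than 20%
discards). Overlap is measured on the protein axis because the final score
is normalised protein-relative. Greedy selection is not guaranteed optimal
for adversarial overlap structures; the test suite checks it against an
exhaustive maximum-weight oracle and it is optimal whenever all pairs are
compatible, the situation that actually occurs in window searches.

**FTB.** X = 100·TB(plus)/TB(self), Y = 100·TB(minus)/TB(self);
FTB(plus) = X − Y and FTB(minus) = Y − X, so each side's pair is exactly
antisymmetric before filtering and at most one of the two is positive.
Scores above 100 are possible (a window holding several copies sums) and
deliberately uncapped. The small-protein filter — if TB(self) < 250 and
0 < FTB < 50, subtract (250 − TB(self))/4 — is applied per score, not per
CDS, since each of the four scores has its own magnitude. Scores ≤ 0 are
never filtered; the condition is applied exactly as stated.

## Array assembly

A CDS is *significant* on a side when that side carries an FTB score at or
above the threshold (default 10; the useful range is roughly 10–15 — higher
values mostly shed tagged-CDS background rather than arrays). Two CDSs at
rank distance 1 (or 2, across one permitted spacer gene) are adjacent when
the left one's downstream side and the right one's upstream side are both
significant. Arrays are maximal left-to-right runs of adjacency: a CDS
adjacent on both sides occupies a middle position and never splits a run.
Direct rank-1 links are preferred over spacer jumps; a consequence is that
a gene skipped as a spacer may itself have been linkable to its successor —
the greedy pass resolves such ties in favour of the longer bridged array.
Arrays broken by more than one spacer are not merged automatically.

Orientation uses annotated strands when both partners are CDSs
((+,+) sense, (−,−) antisense, (+,−) convergent, (−,+) divergent); an array
whose neighbour pairs do not all share one class is *mixed*. For relic
members the strand is inferred from the FTB match strand: an HSP on the
window's plus strand means the relic is coded on the chromosome's plus
strand, so a relic matching on its partner's annotated strand forms a
direct pair.

S1/S4 are the outward (upstream-of-first, downstream-of-last) positive FTB
scores of an array; S2/S3 are the facing scores of each neighbour pair. An
array with S1 or S4 above threshold is a candidate for starting or ending
with a homologous relic.

## Curation

Tagged CDSs (significant scores but no arrayed partner, or array-edge CDSs
with an extra outward score) are screened automatically:

1. facing pairs of tagged CDSs across ≤ 1 spacer merge into new arrays;
2. the rest are dotplotted (DNA, window 23, stringency 15) against their
   significant flank window — reverse-complemented when the match strand
   differs from the CDS strand. A diagonal run of ≥ 30 consecutive dots
   whose span lies ≥ 50% outside annotated CDSs confirms a gene relic; the
   matched span becomes the relic locus. The 30-dot / 50%-intergenic
   defaults are this package's mechanisation of what is otherwise a visual
   judgement; both are configurable.
3. unconfirmed tags are rejected as false positives.

**Minisatellite screening.** Every member CDS of every array is scanned in
two stages: a fast autocorrelation pass reports unit sizes whose match run
at lag u reaches 20 (units up to 600 bp, multiples of a reported unit
deduplicated), then an exact scorer evaluates candidate units in 10–300 bp:
for every phase and contiguous block of ≥ 2 whole copies, score =
matches − mismatches against the column-majority consensus, ties toward
smaller units then leftmost spans. Repeat units are matched without gaps;
gapped (indel-containing) repeat structures are out of scope, so scores are
not claimed to equal EMBOSS etandem's. Note that with ≥ 2 copies the score
2·matches − copies·unit is non-negative for any random sequence at some
unit, so the exact scorer is meaningful only behind the quick-scan gate or
on explicit candidate units. A flagged array is rejected only if, with all
repeat spans hard-masked (normalising by the *original* self-scores so
masking can only lower an FTB), no neighbour pair keeps both facing scores
at threshold — i.e. the apparent homology was the shared repeat.

## The synthetic test bed

The generator emulates a compact hemiascomycete-like genome: background
genes are codon-sampled from a fixed yeast-like usage table (length
gamma-distributed, mean 1.38 kb, minimum 0.3 kb), packed at one gene per
≈2 kb (intergenic gamma, mean 0.62 kb), strands random, single-exon unless
the optional one-short-intron mode is enabled. Planted structures:

* **arrays** — copies of a founder mutated codon-wise (synonymous-biased,
  substitutions only, so lengths are preserved) until the translated
  identity reaches a target; member spacing is drawn short (150–450 bp),
  modelling the compact spacing of a tandem-duplication unit rather than
  the genome-wide intergenic distribution — a planted "one-spacer" array
  whose geometry exceeded the 3 × L window would be undetectable by
  construction and would test nothing;
* **relics** — a diverged copy degraded by premature stops and/or −1
  frameshifts plus 3′ truncation until no forward-frame ORF covers half the
  original gene, placed unannotated in the intergenic gap flanking its
  array. Truth DNA identity is measured infix-wise (relic vs its
  best-matching region of the source) with edlib;
* **dispersed families** and **minisatellites**, the latter either inside a
  true array's founder (shared by all copies) or as one long repeat shared
  by two unrelated neighbouring genes — a deliberate false tandem pair.

What the generator does *not* emulate: real low-complexity and
compositionally biased proteins, transposons, segmental duplications,
whole-genome duplication and synteny, alternative splicing, assembly gaps.
Passing the recovery benchmark therefore shows the machinery is correct
under the stated geometry and divergence, not that curation thresholds are
tuned for every real genome's repeat landscape.

## Benchmark problem sizes

The standard recovery experiment uses 20 seeded genomes of ≈103 genes each
(76 background genes plus ten planted structures per genome: arrays of
sizes 2–5 at 80–100% identity covering all four pair orientations, one
spacer case, one relic-terminated 2-CDS array and one CDS+relic pair).
These sizes keep a full run to a few minutes on one CPU while giving ≈180
planted arrays and 40 relics per experiment — enough to resolve the ≥95%
recovery and ≥90% confirmation margins. The acceptance script derives its
genome seeds from `--seed` and reports aggregate recovery, orientation
accuracy, relic confirmation, false positives and the threshold-10/15
counts.

## Numerical and degenerate-case policy

* Window lengths use the *spliced* CDS length; the window excludes the full
  genomic span (introns included) and is measured from the outermost CDS
  coordinates, truncating silently at chromosome ends (possibly to zero).
* Trailing partial codons are trimmed with a warning; features shorter than
  one codon are flagged untranslatable and carry null scores.
* Untranslatable or degenerate (non-positive self-score) CDSs never become
  significant and so never join arrays.
* Score tables serialise with fixed 2-decimal formatting; identical inputs
  and configuration give byte-identical files.
* Threshold monotonicity (raising 10 → 15 reduces tagged CDSs and arrays)
  is an empirical property of realistic score tables, not a theorem: on
  adversarial tables a dissolved array can re-tag its members. The property
  test asserts the theorem (the significant set shrinks); the benchmark
  asserts the empirical behaviour on generated genomes.

## Known limitations

* Gapped minisatellite units and repeat copy counts that are not whole
  numbers are not modelled.
* The automated relic confirmation inherits dotplot resolution: relics
  shorter than ~50 bp of conserved DNA, or below ~65% DNA identity, fall
  under the 30-dot diagonal floor.
* The external `tblastn` engine is a fidelity adapter: its bit scores come
  from BLAST's own statistics and differ slightly from the internal
  engine's fixed-parameter scores.
* First isoform per locus only; overlapping gene models are dropped with a
  log message.
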