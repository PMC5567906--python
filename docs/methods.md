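# Methods

## Scope and model of the data

`protomir` implements the analysis chain for an unreplicated two-library
small-RNA sequencing comparison (one library per condition, labelled
`calli` and `protoplasts` throughout). The observable unit is the read
count of a unique insert sequence in each library; all inference is
count-based, with library totals as the only normalization anchor.

## Read cleaning and the category ledger

Each raw read is assigned to exactly one category by the **first failing
test** in a fixed order: low quality → no 3' adapter → empty insert →
5' adapter contaminant → shorter than `min_len` → poly-A → clean. The
order matters only for reads that would fail several tests; fixing it
makes the ledger a partition, so the conservation identity
`clean = high_quality − Σ(removed categories)` is structural, and
`clean_pct` is reported relative to high-quality reads (2 decimals).

Definitions the upstream literature leaves open, chosen here and
configurable:

* *Low quality*: any `N`, any non-nucleotide character, or mean Phred
  < 20.
* *3' adapter detection*: the earliest read position where a ≥ 6 nt
  prefix of the adapter matches with ≤ 1 mismatch; the insert is
  everything 5' of it. A match that would leave an insert longer than
  `max_len` (default 30 nt) is not usable, and such reads are ledgered
  as "no 3' adapter" — the analysis window is 18–30 nt and there is no
  separate over-length category.
* *5' adapter contaminant*: the insert begins with a ≥ 8 nt prefix of
  the 5' adapter (≤ 1 mismatch); detected only when a 5' adapter is
  supplied.
* *Poly-A*: insert with ≥ 80 % adenine.
* The lower length bound is 18 nt. Gel excision in typical protocols
  captures 16–30 nt, but the analysis window is 18–30; both bounds are
  parameters.

## Hierarchical annotation

Unique sequences are classified by the first matching category in the
priority order rRNA > tRNA > snRNA > snoRNA > known miRNA > exon >
intron > unannotated. All matching is exact (deterministic, no scoring
heuristics): ncRNA classes by verbatim containment in a reference
sequence, known miRNAs by full-length equality after U→T/case
normalization (mismatches disqualify — one-off variants fall through to
the genomic categories), genome placement by exact substring search on
both strands, capped at `max_hits` loci (default 25) with an overflow
flag. A genome-mapped read overlapping gene models takes the feature
with the largest overlap (ties favor exons) and is sense/antisense
according to read strand vs gene strand. Duplicate mature sequences
under different catalog names collapse to the first name with a logged
warning. Family labels are derived from the `miRNNN` stem of the name,
so passenger strands (`*` suffix) group with their family.

## Novel miRNA discovery

Unannotated sequences of mature length (20–24 nt) with ≥ `min_reads`
summed support and < `max_hits` genomic loci seed precursor candidates:
a window extending `flank` (150) nt on both sides of the read plus two
read-anchored sub-windows (read near the 5' or 3' end), strand-corrected
to transcribed orientation and clipped at contig bounds. Each window is
folded and screened in fixed order; the first failed criterion is the
rejection reason:

(a) the mature read must lie entirely on one stem arm (its structure
    segment contains only `(` or only `)`, and at least one pair);
(b) ≤ 4 unpaired mature positions, and the asymmetry between the
    mature's paired span and its star span ≤ 2 nt;
(c) window MFE ≤ −18 kcal/mol;
(d) mature length 20–24 nt;
(e) ≥ 5 supporting reads summed over libraries.

Star presence among sequenced reads is *not* required — the criterion
operates on the predicted duplex, as many genuine plant miRNAs lack a
sequenced star. Accepted candidates are deduplicated by mature sequence
(all loci retained) and named `novel_mir_1..N` in (locus, mature) order,
so naming is reproducible run-to-run. Acceptance is monotone in MFE by
construction: deepening the fold energy can only help criterion (c).

Thresholds follow the conventions of the Mireap family of plant
miRNA predictors; all are parameters of `HairpinThresholds`.

## Folding engines

Two engines implement `fold(seq) -> (dot_bracket, mfe)` and
`duplex(s1, s2) -> energy`:

* **ViennaEngine** — nearest-neighbor thermodynamics via the ViennaRNA
  bindings (`RNA.fold`, `RNA.duplexfold`); the default when importable.
* **NussinovEngine** — self-contained maximum base-pairing dynamic
  program (Watson–Crick + G·U, minimum loop 3) with −1.0 kcal/mol per
  pair; O(n³), intended for short sequences and as an
  engine-independent cross-check. Its duplex variant restricts pairing
  to inter-strand partners across an unpairable linker.

The property suite verifies the Nussinov engine against an independent
recursive maximum-pairing computation and checks that the
thermodynamic engine never exceeds that pairing bound.

## Differential expression

TPM = 10⁶ · count / library total, where the total is the library's
clean-read count by default (normalizing by miRNA-mapped reads instead
is a parameter). TPM below 0.01 is floored at 0.01 so
condition-specific miRNAs keep finite fold changes (an absent miRNA at
~15 M reads yields |log₂FC| ≈ 10–13 against a moderately expressed
partner, matching the magnitudes such studies report). The effect size
is log₂(TPM₂/TPM₁); significance is the exact conditional test for two
Poisson totals,

    P(Y=y | X=x) = (N₂/N₁)ʸ (x+y)! / ( x! y! (1+N₂/N₁)^{x+y+1} ),

with a two-sided p from doubling the smaller of P(Y≤y|x) and P(Y≥y|x),
capped at 1. Both tails are direct summations in log-gamma space (the
upper tail is summed upward in blocks until the remaining geometric
mass is negligible), never computed as one-minus-the-other, so extreme
tails keep full relative precision. Note the test conditions on the
first count, so it is *not* exchange-symmetric in (x, y) — p(0,1) = 1
but p(1,0) = 0.5 at equal totals; this is a property of the statistic,
not an implementation artifact. Calls use a strict fold-change cutoff
(|log₂FC| > 1) and an inclusive p cutoff (p ≤ 0.01); no
multiple-testing correction is applied, matching the practice of the
unreplicated-library literature this implements. Reports round TPM and
fold change to 2 decimals and print p in scientific notation.

## Target prediction

A miRNA is aligned antiparallel against every transcript window, each
miRNA position (1-based from the 5' end) classed W/G/M/B (Watson–Crick,
G·U, mismatch, bulge). At most one single-nucleotide bulge is allowed,
weighted 1.0 and prohibited within positions 2–12; target-side bulges
are recorded against the 5'-flanking miRNA position. Windows whose best
alignment scores ≤ 4 (G·U = 0.5) are kept, one alignment per distinct
window, so overlapping window variants of one site appear as separate
rows. The six acceptance rules are listed in the README; two readings
the source criteria leave open are resolved conservatively and exposed
as switches: G·U counts as a mismatch *event* for the positional rules
(2)–(4) while weighing 0.5 in the scores, and "no more than 2 adjacent
mismatches" is read as forbidding runs of three or more consecutive
non-paired positions. The energy rule compares `RNA.duplexfold` (or the
fallback engine) on the window against the miRNA's perfect complement:
accept when duplex MFE ≤ 0.75 × perfect MFE in signed kcal/mol,
equivalently ratio ≥ 0.75; a non-negative duplex energy yields ratio 0.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions; its defaults were fixed once, on the following grounds:

* **Genome and hairpins**: one 100 kb toy chromosome, 30 planted
  precursor loci (20 in the known catalog, 10 discoverable as novel) at
  well-separated slots on random strands. Precursors are perfect
  inverted repeats (6–10 nt flanks, 8–12 nt loop) hosting the mature on
  one arm, so the mature/star duplex provably satisfies the hairpin
  screen; each mature and its complement occur exactly once on the
  chromosome (verified at build time).
* **Expression**: per-miRNA abundances on a log-uniform grid
  10^0.8–10^2.2 (the top species holds ~10 % of miRNA reads, like the
  dominant conserved family in real callus libraries); counts are
  negative-binomial with dispersion 0.05 — between Poisson and
  biological-replicate variability, appropriate for two technical
  library preparations. Planted log₂ effects (±3, ±2, alternating sign,
  up to six per group) multiply protoplast means and go to species
  holding 0.4–3 % of the miRNA mass: published DEMs sit in this
  mid-abundance range, effects on near-zero species are unobservable,
  and effects on dominant species distort whole-library composition.
* **Contamination**: defect fractions mirror per-category rates of
  deeply sequenced libraries (10⁻⁴–10⁻³ of reads), 5 % ncRNA
  fragments, 55 % genome degradation fragments of 15–30 nt (those
  < 18 nt are truth-ledgered as "shorter than 18 nt"). Degradation
  fragments are required to map uniquely so annotation truth is
  unambiguous; every constructed insert is verified to trim back to
  itself through the actual adapter detector, which is what makes the
  ledger truth exact rather than approximate.
* **Targets**: transcripts carry planted sites — reverse complements of
  their cognate matures, half with one G·U wobble in the 3' region —
  verified against the rule filter at construction.
* The read budget is exact: defect, ncRNA and miRNA counts are drawn
  first and degradation absorbs the remainder, so category counts sum
  to `n_reads_per_library` identically.

What the generator does **not** emulate: sequencing errors and quality
variation, multi-chromosome genomes, imperfect hairpins
(bulged/mismatched stems), repeat families, isomiR heterogeneity, and
biological replicate variance. Passing round-trip tests therefore
demonstrates the pipeline's bookkeeping, criteria and statistics are
correct — not that the hairpin screen or the exact test would attain
the same recall on noisy real libraries.

## Problem sizes and numerical choices

The bundled test suite runs the generator at 2 × 20,000 reads and the
shared end-to-end fixture at 2 × 50,000; the acceptance script runs
2 × 100,000 — sizes chosen so expected counts (≥ ~30 reads for effect
carriers at the smallest size) support the recall properties being
demonstrated. p-value tails terminate when a summation block falls
below 10⁻¹⁸ of the accumulated mass; oracle comparisons demand ≤ 10⁻¹⁰
relative error. Ties in exon/intron overlap go to exon; duplicate
catalog sequences keep the first name; candidate deduplication keeps
the first locus in coordinate order. All randomness flows from a single
integer seed through `numpy.random.default_rng` with fixed per-stage
salts, making every pipeline output byte-identical for a fixed
configuration.

## Known limitations

* Exact-match annotation misses variants one substitution away from a
  reference (by design, for determinism); there is no seed-and-extend
  or BLAST-like fallback.
* The hairpin screen evaluates windows independently; overlapping loci
  from the same read are resolved by first acceptance, not by best
  energy.
* The exact test inherits the unreplicated design's weakness: with
  real biological overdispersion its p-values are anti-conservative,
  and the pipeline deliberately applies no multiple-testing
  correction.
* Target prediction enumerates all windows (O(transcript × miRNA
  positions)); it is intended for transcript sets of thousands, not
  whole transcriptomes, at interactive speed.
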