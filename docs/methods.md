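# Methods

This note documents the models, conventions and numerical choices behind
bambuseq, in the spirit of a software methods supplement. Everything
quantitative stated here is computed by the test suite or the examples;
nothing is asserted beyond what the code reproduces.

## Coordinate and sequence conventions

All internal intervals are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted exactly once at the I/O boundary (`seqio`), so
off-by-one errors cannot accumulate. Transcript-level analyses operate in
transcription orientation; genomic intervals keep scaffold orientation,
with minus-strand exons listed 5′→3′ in transcription order. DNA is
restricted to A/C/G/T/N; other IUPAC ambiguity codes are collapsed to N
with a warning, because downstream gap filling relies on exact string
matching over a small alphabet. Event positions are reported as the
0-based reference coordinate of the base *preceding* the event; premature
stops additionally carry a 1-based alignment column, the idiom used in
comparative reports.

## Synthetic data as study conditions

The generator (`synthetic`) is not a test fixture but the package's
definition of the data regime it targets:

- **Gene models.** 4–9 exons of 90–400 bp by default (configurable, or
  fixed exactly via `exon_lengths`), GT..AG introns of 80–800 bp, CDS
  starting ATG, ending in a single stop, free of internal in-frame stops,
  length divisible by 3. Half the genes sit on the minus strand.
- **Orthologs.** Substitutions are i.i.d. per base, uniform over the three
  alternatives, at probability `divergence`; expected identity is exactly
  1 − divergence. The regime of interest is divergence 0.15–0.27
  (≈ 85–73% CDS identity, the range typical of rice–bamboo orthologs).
  Substitutions that would create an in-frame stop in the reference frame
  are resampled (`avoid_stops`), so premature stops arise only from
  planted frame disruptions — keeping the pseudogene ground truth
  unambiguous. The start and terminal-stop codons are never mutated.
- **Planted events.** Insertions (random sequence; `stop_free` restricts
  the inserted run to A/C/G so it cannot itself contain a stop),
  deletions, and retained introns (the gene's own intron sequence inserted
  at its junction). Event footprints are excluded from the substitution
  pass so each difference is attributable to exactly one cause.
- **Fragmentation.** The mutant transcript is cut into n contigs whose
  union misses exactly one internal gap (default 3 contigs, 120 bp gap).
  Breakpoints and the gap keep `event_margin` (default 150 bp) away from
  planted-event footprints: affine-gap mapping needs a solid exonic anchor
  on both sides of a long retained intron (the score break-even is ~75 bp
  at divergence 0.27), and a smaller margin makes contig projection
  ambiguous for reasons that belong to the aligner, not the scanner. On
  transcripts too cramped for the margin it relaxes stepwise with a
  warning.
- **Reads.** Fixed-length paired-end reads (default 2×100 bp, insert
  200–300 bp, depth 20×), uniform positions and strands, i.i.d.
  substitution errors. No quality model, GC bias or isoform structure is
  simulated; conclusions from passing tests therefore speak to assembly
  fragmentation and sequence divergence, not to raw-data artifacts.
- **Counts.** Genes are assigned evenly to k archetypes (default 9); each
  archetype is "on" (fold 32) in a distinct tissue subset of the 6-tissue
  × 3-replicate layout. Per-gene lognormal abundance factors multiply the
  archetype means; counts are gamma–Poisson (negative binomial) with
  dispersion 0.05. Dispersion 0 is the exact Poisson limit; negative
  dispersion is an error. Outlier libraries are made by permuting a clean
  library's gene labels — preserving its marginal count distribution while
  destroying all correlation, which is precisely the failure mode replicate
  QC must catch.

All generators are pure functions of (config, seed); identical inputs give
byte-identical artifacts.

## Curation

The longest-ORF scan requires ATG and an in-frame stop inside the contig
(open-ended ORFs are not counted) over all six frames, ties resolved
deterministically (+1,+2,+3,−1,−2,−3; 5′-most wins; only strictly longer
replaces). The ORF filter is strict (> 200 bp). Representative selection
keeps the longest contig per (assembly component, orthogroup) pair —
unassigned contigs group by component alone — with lexicographic id as the
tie-break. N25/N50 use the cumulative-sum definition. The UCO capture
percentage is *truncated* (not rounded) to one decimal, the convention
completeness tables in this field typically use.

## Expression

FPKM(g,l) = counts·10⁹ / (length·library total); the log transform is
log2(FPKM+1) — the pseudocount keeps zeros finite. MAD ranking is unscaled
(no 1.4826 factor) because only the order matters for top-n selection;
ties break by gene id. Distances are 1 − Pearson r (range [0,2]);
clustering is complete linkage on the precomputed distance matrix, cut
with `maxclust`, labels renumbered by first appearance. k is a user
parameter (default 9), never auto-selected.

**Replicate QC** replaces multiscale-bootstrap p-values with plain
bootstrap co-clustering: genes are resampled with replacement, libraries
are re-clustered, and a library "co-clusters" in one bootstrap when,
walking up the merge tree from its leaf, a same-group replicate appears
while the cluster still has at most the group's size members. The size
cap matters: a corrupted library that merges last into the all-library
cluster meets its replicates there trivially, and must not be credited.
Support below 0.5 over (default) 1000 bootstraps flags the library.

**Differential expression** is a deliberately lightweight stand-in for a
full shrinkage-based NB framework: median-of-ratios size factors,
per-gene method-of-moments NB dispersion *floored at the across-gene
median* (unfloored 3-vs-3 moment estimates are noisy enough to inflate
type-I error severely), and a normal-approximation Wald test on the log
fold change of normalized means (pseudocount 0.5; genes with all-zero
counts get p = 1, log2FC = 0). Calibration is verified by simulation: on
2,500 null NB genes (3v3, dispersion 0.05) the fraction with p < 0.01
stays within [0.005, 0.02], and planted 4-fold changes at mean ≥ 100 are
recovered at ≥ 90% with the p < 0.01 / fold-change-2 rule. Thresholding
uses the raw p-value, with Benjamini–Hochberg adjusted values reported
alongside (BH is used wherever an adjusted p appears).

Enrichment is the hypergeometric upper tail P(X ≥ k), exact against
subset enumeration (verified for all background sizes ≤ 12). qPCR
quantification averages technical replicates first, then
2^−(CT_target − mean CT_references).

## Alignment engine

All DNA alignments share one scoring scheme: match +2, mismatch −3, and an
affine gap costing 16 + 0.5(k−1) for a k-base run — a *high-open,
cheap-extend* profile rather than the BLAST-like −5/−2. The reason is
quantitative: with extension at −2/base, placing a 300–700 bp retained
intron as one gap costs far more than "scattering" it across the reference
via chance matches (~−0.7/base), so any optimizing aligner will shred long
insertions. Cheap extension (−0.5/base) makes the honest long gap optimal,
while the high open cost (−16) keeps 1–2 bp spurious gaps dearer than
mismatches. Protein alignments use BLOSUM62 with −11/−1.

**Contig mapping** aligns each contig end-to-end (both strands) while
reference end gaps are free ("infix" alignment), so diverged contig
termini are still projected onto the reference and planted fragmentations
stitch back base-perfectly. Because unrelated contigs are then forced
through a fully penalized alignment they score hundreds of points
negative, and a small positive threshold (default 20) cleanly rejects
them even though a genuine intron-bearing contig's score is mostly
consumed by its gap.

**Stitching** places contig bases at reference-projected positions;
uncovered reference spans become N runs with exactly matching gap
records; insertions ride along anchored to their preceding reference
base. Conflicting overlap positions take the base from the block with
higher identity (exact ties emit N), and two contigs disagreeing over
more than 20% of their shared positions raise an error listing the
positions. The output is independent of block input order.

**Gap filling** is greedy single-path consensus: the terminal `seed_len`
(default 25) bases of each flank seed exact-match searches over the reads
(both strands by default); extension proceeds by majority consensus where
at least `min_read_support` (default 2) reads agree and halts on any
support tie — ambiguity is reported, never guessed. A gap closes when the
converging extensions overlap exactly over ≥ seed_len bases; a terminal
gap (empty flank) closes open-ended when its surviving side stops
extending. Non-gap bases are never modified, and each filled base is
tagged with the iteration that produced it. One iteration advances at
most read_len − seed_len bases per side, so a gap of 2.5 × (read_len −
seed_len) with one-sided extension closes in exactly three iterations — a
geometry the test suite pins down.

**Genomic recovery** locates a CDS query with edlib (fast bit-parallel
edit distance) on both strands, then re-aligns within a padded window
using the infix aligner above — the two-step split exists because unit
edit costs price an intron deletion like a run of mismatches and
therefore cannot recover intron structure. Target-side gap runs ≥ 30 bp
become introns; boundaries are snapped to the nearest GT..AG pair within
±10 bp, preferring donor/acceptor shifts that preserve total exon length.
The reading frame is whichever six-frame translation of the concatenated
exons best aligns to the query peptide. Peptide queries are chained
per-frame local protein alignments split at intron-scale target gaps;
they resolve boundaries to codon precision (and cannot see the terminal
stop codon), so CDS queries are preferred when available.

**Finalization** picks the frame whose translation best matches the
reference peptide, trims to ATG..stop, and flags (never silently trims) a
missing start, missing stop, remaining gaps, or a stop truncating more
than 5% of the reference protein. Identity is matches / alignment columns
including gap columns — a declared convention, since published identity
figures rarely state theirs.

## Pseudogene scanning

`detect_indels` reports one event per maximal gap run (insertion = gap in
the reference row). A normalization pass (`merge_adjacent_indels`, window
20 reference bp) then fuses same-kind runs that affine alignment split
through gap attraction — without it, a planted 8-bp insertion inside a
diverged sequence occasionally surfaces as 3+5 or 6+2 — restoring the net
event whose length mod 3 is the frame offset. Premature stops are found
by walking the query in codons from the base aligned to the reference
ATG; a stop strictly before the reference's terminal-stop column is
premature, reported with CDS position, 1-based alignment column and
truncated fraction. Insertions reclassify as retained introns when they
fall within ±20 bp of an annotated exon–exon junction (gap placement
slides within locally similar sequence, so ±2 bp is too tight in
practice) *and* match that intron's length within ±5%; GT..AG termini are
recorded as corroboration but not required. With reads supplied, an event
is marked supported when ≥ 2 reads contain the variant-spanning query
window; without reads the flag stays unset rather than false.

Classification is a pure function of the event set: a frameshift indel
with a downstream premature stop truncating ≥ 5% of the reference protein
→ `frameshift_pseudogene`; a qualifying stop alone → `truncated`;
retained introns only → `retained_intron`; frame-preserving indels →
`in_frame_variant`; otherwise `conserved`. The 5% floor keeps
near-terminal polymorphic stops from being called pseudogenes.

## Pipeline

`run_pipeline` derives per-stage seeds by hashing the stage name with the
global seed, so toggling one stage never shifts another's randomness. The
report's `results` section is byte-identical across runs with the same
config and seed; wall-clock timings live in a separate `timing` section
outside that guarantee. A failure in one gene's reconstruction or scan is
recorded per gene and does not abort the rest.

## Problem sizes

Defaults used throughout the tests and examples: 20 genes of 6–12 exons
for reconstruction studies; 4,500 genes × 18 libraries for clustering;
2,000–2,500 genes for QC and DE simulations; genomic scaffolds of ~10–20
kb for recovery tests. These sizes make every property checkable exactly
against planted truth while each individual analysis remains interactive.

## Known limitations

- The scanner calls events from assembled or reconstructed sequence;
  reads only corroborate, they never call events on their own.
- The DE stand-in has no dispersion shrinkage across genes beyond the
  median floor and no regularized log transform; it is calibrated for the
  simulated regime, not a replacement for a full NB framework on real
  data.
- The uniform substitution model treats all sites alike, so protein
  identity of simulated orthologs runs lower than real orthologs of equal
  nucleotide identity (no purifying-selection structure).
- Splice-site snapping assumes canonical GT..AG introns.
- Gap filling is single-path: repeats longer than the seed length within
  a gap region halt extension rather than branching.
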