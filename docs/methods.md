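# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each stage of the pipeline. Defaults are stated with
units; everything listed is configurable unless said otherwise.

## Coordinates and formats

All in-memory intervals are 0-based half-open. GFF3 and AGP are written in
their native 1-based inclusive conventions; the converters are exact
inverses, and round-trip equality is enforced by tests. Minus-strand
features are stored on forward coordinates with a strand flag and are never
reverse-complemented at parse time. Negative template-projected gaps are
serialized as 1-bp `N` rows flagged `overlap_suspected` in a trailing AGP
comment, since AGP itself cannot express a negative gap.

## Anchor alignment

Anchors are local alignments between query contigs/clones and the template.
The implementation seeds with exact 13-mers on both strands (soft-masked
bases never seed; extension may cross them), clusters seeds into diagonal
bands (+-100 bp) and splits each band into runs at q- or t-gaps above
400 bp. Each run, padded by a 100 bp margin and capped at ~2 kb of query
span per window (windows butt-join at seed midpoints), is aligned with a
full affine-gap Smith-Waterman (Biopython's C `PairwiseAligner`): match +1,
mismatch -2, gap open -5 plus -2 per base. A window reports only its
optimal local alignment, which is why runs get their own windows — a weak
match sharing a window with a strong one would otherwise be silently
dropped, and duplicated-copy evidence is exactly such a weak match.

Two post-passes shape the hits:

* alignments are split at internal gaps longer than 100 bp, so a hit's
  interval is contiguously aligned territory — without this, the aligner
  happily bridges a few-hundred-bp insertion and the bridged span would be
  mistaken for aligned sequence by the rearrangement rules;
* exactly abutting window hits (shared junction on both axes) are fused;
  for a gap-free junction the scores are additive, so the fused score is
  still the score of a single local alignment of the fused intervals. A
  query identical to a 10 kb template slice therefore reports as one
  10 000-point hit.

Raw scores convert to bits as `bit = (lambda * raw - ln K) / ln 2` with
declared constants lambda = 1.28, K = 0.46 matched to the +1/-2 scoring;
hits at or below 200 bits are discarded, mirroring the collinearity filter
the analysis is built around. The bit threshold corresponds to a raw score
of ~108, i.e. roughly 110 bp of perfect match or ~150 bp at 10% divergence —
this detectability floor matters for the event-length model below.

Chaining finds the maximum-bit-weight collinear chain per (chromosome,
strand) by O(n^2) dynamic programming, tolerating 50 bp of anchor overlap
and gaps up to 20 kb on either axis; ties break toward the leftmost
template coordinate. An exhaustive subset oracle validates chain weights on
small instances.

## Template-guided scaffolding

Contigs are deduplicated first: a contig whose identity-weighted alignment
coverage by a longer kept contig reaches 0.9 is removed (duplicate,
overlapping and embedded assemblies all fall out this way). Each remaining
contig is placed at its heaviest chained locus; a contig whose second-best
locus (other chromosome/strand, or a second chain on the same one) reaches
within a factor 2.0 of the best is left unplaced as `multi_locus`, and
contigs disagreeing with the clone's dominant chromosome are unplaced as
`conflict`. Orientation is the chain strand.

Placed contigs are ordered by the bit-weighted *centre* of their chain's
anchors rather than the projection start: a stray duplicated-source anchor
can extend one projection edge, and the centre is robust to that. Residual
projection overlaps are trimmed from the lower-weight contig, then a final
sweep clamps any leftover (e.g. nested) overlap. Gaps are template
distances between adjacent projected ends; negative gaps are flagged
`overlap_suspected` and gaps strictly below 2 kb `closable` (the
primer-walkable regime).

Summary fractions follow the clone-table arithmetic: ordered bp over insert
bp, aligned (spanned) query bp over insert bp, and template expansion
`(spanned_template - spanned_query) / spanned_query`. The insert estimate
is the default denominator because the printed ordered fraction is
reproduced by exactly that ratio; a flag switches to the
unambiguous-contig total.

## Rearrangement classification

The main chain is the syntenic frame. Off-chain hits that continue each
other (same strand/chromosome, gaps <= 150 bp on both axes) merge into one
event block, then each block is classified:

* covered >= 0.5 by chain *template* intervals but not by chain *query*
  intervals → `duplication_query` (an extra query copy of template
  territory the chain already explains);
* the converse → `duplication_template`;
* opposite strand, inside the frame's template span (+- 1.5 kb margin) →
  `inversion`;
* opposite strand, out of place → `inverted_translocation`;
* otherwise → `translocation`.

Coverage against chain intervals (not reciprocal overlap with single
anchors) is deliberate: chain anchors are large merged blocks, so a
duplicated segment is *contained* in them rather than matching one
one-to-one. Event length is the aligned bp of the block (template-side bp
for `duplication_template`, whose extra copy lives on the template). Each
block receives exactly one class, so classification partitions the
off-chain evidence. Inversion polarity is relative to the template; without
an outgroup the genome of origin is not inferable and reports say so rather
than guessing. Indels are deliberately absent from the event table — they
are too numerous to enumerate meaningfully and appear only as unaligned bp.

Tandem-duplication detection is annotation-level: ortholog pairs define
gene families (connected components of a many-to-many map); a family is
reported when copy counts differ between genomes and the multi-copy side is
a genuine tandem array (same sequence and strand, adjacent copies <= 20 kb
apart).

## Repeats and SSRs

Masking aligns a labelled consensus library against the input with the
anchor aligner at a 50-bit threshold (~35 bp of match); overlapping family
claims resolve by bit score and no base is ever counted for two families.
The family taxonomy is frozen (SINE, LINE/L1-CIN4, LTR/Copia,
LTR/Gypsy-DIRS1, four DNA-transposon families, Tourist/Harbinger,
Unclassified) so summaries are comparable across runs; unknown labels map
to Unclassified. Simple repeats (the SSR detector's loci) and
low-complexity runs (Shannon entropy < 1.5 bits/base over 64-bp windows,
half-window step, merged) are tallied and masked after family claims.
Masked bases never seed, so masking is idempotent.

SSRs are perfect maximal tandem runs of a primitive 1-6 bp motif with copy
minima 12/6/4/3/3/3 (mono through hexa), partial trailing copies included
(`copy_number x motif length = run length` holds exactly). Overlapping
candidates keep the longest run, then the shortest motif. Motifs are
canonicalized to the lexicographically minimal rotation over both strands,
making the locus set invariant under reverse complement. 200 bp flanks are
extracted for primer design and flagged when truncated by a sequence end.

## NG86 and the molecular clock

Ortholog pairs are aligned at the protein level (Needleman-Wunsch, BLOSUM62,
gap open -10 / extend -1) and back-mapped to codons, so frame is preserved
and every gap is a codon triplet. Columns with gaps or ambiguous bases are
excluded from counting. Pairs with internal stops, fewer than 50 aligned
residues or below 50% protein identity are rejected as unreliable
(declared thresholds).

NG86 proper: per-codon synonymous site fractions count, at each position,
the fraction of the three single-base changes that preserve the amino acid;
changes producing stop codons count as nonsynonymous, so S + N = 3 per
codon. Multi-position codon differences are averaged over all substitution
orderings with pathways through stop codons excluded (if every ordering is
blocked — possible but rare — the average over all orderings is used). The
Jukes-Cantor correction `d = -(3/4) ln(1 - (4/3) p)` maps proportions to
distances; `p >= 3/4` raises a saturation error. The implementation uses
precomputed 64 x 64 tables; its correctness criterion is exact agreement
(1e-9) with a brute-force pathway enumerator written independently in the
tests, plus a cross-check against Biopython's `cal_dn_ds` restricted to
pairs where the two pathway conventions coincide.

The clock is `T = Ks_median / (2 r)` with r = 6.5e-9 synonymous
substitutions/site/year (the standard grass-lineage rate), exposed as a
parameter. The median uses the lower of the two central values for even
counts — a declared convention, since "the median" is otherwise ambiguous.
Median Ks 0.10 / 0.53 / 0.58 date to 7.7 / 40.8 / 44.6 Myr.

## Pool deconvolution

Evidence is shared canonical minimizers (k = 21, window w = 11, canonical =
min of a k-mer's code and its reverse complement's, so read strand is
irrelevant). A row-pool read is assigned to column c iff it shares >= 3
minimizers with the reads of exactly one column pool (symmetrically for
column reads); several supporting pools → ambiguous, none → unassigned.
The three categories partition the reads, and ambiguous reads are excluded
from per-clone bins rather than multi-assigned. The grid shape is a config
value; the default is 4 rows x 5 columns, and either orientation yields the
same 9 pools for 20 clones.

Assignment completeness is a coverage property, not an algorithmic one: a
read needs ~40 bp of overlap with opposite-pool reads to clear the
3-minimizer bar, and with per-pool coverage c the chance a read finds no
such overlap scales like e^-1.8c. The shipped scenarios use >= 16x clone
coverage (8x per pool), where the failure probability is negligible;
at ~8x clone coverage occasional unassigned reads are expected and correct
behaviour.

## The synthetic-data generator

The generator's defaults encode the study conditions the pipeline targets:

* template: 1 gene / 10.1 kb (Poisson-placed multi-exon genes with valid
  start/stop and GT..AG introns), 27.6% labelled repeat content drawn from
  the family taxonomy at field-realistic proportions (LTR elements
  dominant), realized fraction within +-3 points of the target;
* clones: insert sizes 40-165 kb, target synonymous divergence Ks = 0.10,
  64x read coverage on a 4 x 5 grid, 17/209 clone-specific gene rate,
  repeat contraction of 207 bp per clone kb (which makes the template look
  ~20% expanded over aligned regions) and clone repeat content steered
  toward 25.5%;
* rearrangement spectrum per clone set: 7 translocations, 4 inverted
  translocations, 3 inversions, 26 query-side and 14 template-side
  duplications, with per-class mean lengths 275/392/281/467/328 bp.

Substitutions use a uniform model with transition:transversion 2:1. Inside
CDS they are codon-aware: synonymous changes are always accepted,
nonsynonymous ones with probability omega = 0.3 (purifying selection), and
changes creating stops are rejected. The substitution rate is calibrated by
closed loop against the package's own NG86 implementation (binary search on
the rate, replaying the same RNG stream per trial so realized Ks is
monotone in the rate). omega = 0.3 is what places exon identity near 95%
when Ks = 0.10 — a neutral model would put it near 93% — and the generator
holds that calibration (95.2 +- 1.5 checked by test). For the standalone
ortholog-pair generator, calibration runs on a separate, larger draw
(120 CDS of 200 codons) and the returned pairs come from a fresh stream, so
measured recovery is honest rather than a replay of the calibration.

Event lengths are shifted-geometric: a 200 bp floor plus a geometric excess
chosen so the per-class mean is preserved. A plain geometric with these
means would put roughly a third of events below the ~110-150 bp
detectability floor implied by the 200-bit filter, making high recall
impossible under the pipeline's own declared filter; the floor keeps the
printed means while keeping events visible.

Template-side duplications need two similar template intervals, which a
random template lacks; the template generator therefore plants dispersed
near-duplicate segment pairs (2% diverged, <= 15 kb apart, recorded in
truth) and the clone builder deletes one copy from any clone whose interval
contains a pair — including pairs only half-inside, which are genuine
template-side duplications too and are recorded as such. Event intervals
and translocation/duplication sources avoid genes, repeats and planted
pairs: repeats are masked before anchoring, so evidence placed inside them
would be systematically invisible, and a source overlapping a planted pair
would yield two template matches for one event. Small indels (rate 2e-4/bp,
geometric mean 3 bp) fall only outside exons so implanted ortholog pairs
stay in frame; per-segment offset tables map gene coordinates into the
clone exactly.

Reads are sheared uniformly, each read going to its clone's row pool or
column pool with equal probability; truth records every read's clone.
Probe tables plant, per clone, two single-copy probes within 50 kb on the
template with hybridization counts in the 10-12 homolog band, plus
distractors of every rejectable kind (multi-copy, short-identity,
out-of-band, partnerless).

Everything is driven by one seed; identical seeds give byte-identical
outputs.

### What the generator does not emulate

No sequencing error model (homopolymer errors, chimeras), no heterozygosity
within the template, no gene-strand variation (all simulated genes lie on
the forward strand; strand handling is exercised through contig orientation
and inversion events instead), no nested/fragmented repeat structure, and
repeat divergence from consensus is uniform rather than age-stratified.
Passing recovery tests therefore demonstrates the pipeline's logic under
the study's statistical structure, not robustness to raw-read artefacts —
on real data, assembly and base-error handling happen upstream of this
package.

## Problem sizes in tests and the acceptance script

The shipped scenarios run the generator at 0.2-0.6 Mb of template, 4-8
clones and 8-32x coverage — a deliberate choice that keeps every recovery
experiment comfortably reproducible on a laptop while preserving all the
rates, fractions and spectra above. The published-scale fractions
(ordered/aligned/expansion percentages, gene density, event-table means,
clock times) are recomputed from the printed totals as inputs, which is an
arithmetic check of the summary machinery, not a re-estimate from raw data.

## Known limitations

* The 200-bit filter's score system is declared (lambda, K matched to the
  +1/-2 scoring), not inferred from the original analysis tooling, so bit
  values are comparable within this package only.
* Per-window single-best-alignment reporting can still drop a weak match
  that shares both its diagonal run and its window with a stronger one;
  in practice the run-splitting makes this rare.
* NG86 is a counting method; no rate variation among sites or codons, and
  no maximum-likelihood alternative is provided.
* `duplication_query` vs `duplication_template` classification depends on
  the chain having aligned the shared locus; if the shared copy itself
  falls below the bit threshold the event degrades to a translocation call.
* The deconvolver assumes two-axis pooling; higher-dimensional pooling
  designs are out of scope.
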