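# Methods

## Coordinate and sequence conventions

All in-memory coordinates are 0-based half-open on the forward strand of
both query and target; conversions happen only at format boundaries.
BLAST tabular (`-outfmt 6`) input is 1-based inclusive and encodes a
minus-strand hit by a subject interval with start > end; the reader
swaps and shifts these on ingestion (the convention was verified against
blastn 2.x output). PAF already matches the internal convention and its
strand column is trusted. Duplicate sequence ids are a hard error —
every downstream structure indexes by id. Lowercase (soft-masked) bases
are preserved through I/O; every analysis is case-insensitive.

## Chromosome building

**Mapped length.** The assignment ratio divides the length of the
*union* of a scaffold's query intervals against one chromosome by
`min(scaffold_length, chromosome_length)`. Merging before summing is
deliberate: overlapping local alignments (HSPs) counted separately could
push the ratio past 1 and bias assignment toward repeat-rich
chromosomes.

**Threshold.** Strictly greater than 0.5 by default (configurable). A
ratio of exactly 0.5 leaves the scaffold unplaced.

**Tie-breaking.** Equal ratios break by larger total aligned bases, then
lexicographically smaller chromosome id. Both keys are deterministic, so
repeated runs produce byte-identical output. A scaffold exceeding the
threshold on two chromosomes is flagged `multi_chromosome_ratio` (and
`possible_chimera_no_joint` when it has no N joint to split at).

**Orientation and order.** Orientation is the strand with the majority
of aligned bases (tie → `+`). The order key is
`Σ aligned_bases·midpoint(t_start, t_end) / Σ aligned_bases` over the
winning chromosome's hits — a robust centre of mass that tolerates a
few stray hits better than, say, the minimum target coordinate.

**Chimera handling.** A scaffold is decomposed at N runs of length ≥
`min_gap` (default 10, the NCBI convention for a spanned gap; the joints
the generator plants are 100 Ns, so both are honoured). Hits are
re-attributed to the segment containing the majority of their query
interval — an exact 50/50 straddle goes to the left segment — then
clipped to the segment and rebased; the target interval is left
untouched because only its midpoint is consumed downstream. Each segment
is assigned independently on its own length. Only when two or more
segments land on *different* chromosomes is the split committed;
otherwise the whole-scaffold verdict stands, so internal gaps alone
never fragment a scaffold. Conflicting mappings without an N joint are
flagged and assigned to the best chromosome, never split: without a
joint there is no defensible split coordinate.

**Rendering.** Per chromosome, segments are concatenated in order-key
order with a fixed 500-N separator (configurable); minus-orientation
segments are reverse-complemented at render time. AGP v2.1 output tiles
`[1, rendered_length]` exactly with W component lines and N gap lines.

## Correction of an existing assembly

A chromosome is **kept** when (a) ≥ `keep_fraction` of its non-N bases
are covered by merged alignments to its name-matched template chromosome
and (b) none of its N-gap-delimited contigs is assigned by the ratio
rule to a different chromosome. Condition (b) exists because coverage
alone is size-blind: a short foreign contig riding inside a long host
chromosome barely dents fractional coverage but is precisely the
mis-scaffolding signature the pass must catch. `keep_fraction` defaults
to 0.95; it is an operational stand-in for "completely mapped" and is
exposed as a tunable, with the boundary kept inclusive (coverage exactly
at the fraction is kept). Chromosome-name correspondence is identity by
default with an optional rename map (covering the case where one
template chromosome comes from a different assembly than the rest).

Everything not kept is decomposed into contigs between its qualifying N
runs. The contig pool (split + unplaced) is then assigned to the
template chromosomes that were *not* kept — the missing or mis-assembled
ones; kept chromosomes pass through byte-identical, so nothing may be
appended to them — and rebuilt with the builder's orientation, ordering
and 500-N concatenation. Contigs assigned nowhere stay unplaced; a
whole unplaced record that survives intact keeps its original id, so
correcting an already-correct assembly is exactly the identity. The
rebuild report gives, per rebuilt chromosome, the template non-N length,
the contributing contig count with a per-source breakdown, the rebuilt
non-N length and the percentage `100·rebuilt/template`, rounded half-up
to 2 decimals (it may exceed 100 when the rebuild recovers sequence the
template lacks).

## QC metrics

* **Nx.** Smallest cutoff L, scanning from the longest sequence down, at
  which the total length of sequences ≥ L reaches x% of the assembly;
  contigs are obtained by splitting at N runs ≥ `min_gap`, shared with
  the builder so "contig N50" is internally consistent. No minimum-length
  filtering is applied (tools such as QUAST may drop short sequences
  before computing N50, so small differences against such tools are
  expected).
* **GC.** `100·(G+C)/(A+C+G+T)`; N and the other IUPAC ambiguity codes
  are excluded from numerator and denominator; an all-ambiguous sequence
  reports a missing value.
* **Placement rate.** `100 · nonN(chromosomes) / (nonN(chromosomes) +
  nonN(unplaced))`.
* **k-mer QV.** Canonical k-mers (lexicographic min of k-mer and reverse
  complement), counted exactly in a hash map — at the multi-Mb scales
  this package targets, probabilistic counting would buy nothing. With
  `K_total` assembly k-mers (with multiplicity) and `K_shared` of them
  present among reliable read k-mers, the per-base survival is
  `P = (K_shared/K_total)^(1/k)` — the k-th root undoes the fact that
  one substitution corrupts up to k overlapping k-mers — and
  `QV = −10·log10(1−P)`. A fully supported assembly returns the cap
  (99.0 by default, reported as "≥ cap") rather than infinity, keeping
  reports numeric. `reliable_threshold` defaults to 2, dropping
  singleton read k-mers, which at real read coverage are dominated by
  sequencing errors.
* **k-mer completeness.** Distinct counting: the fraction of distinct
  reliable read k-mers present in the assembly.

## Synthetic genomes and what they do (not) show

One `numpy` Generator seeded by a single integer drives every choice;
no global RNG state is touched, and all outputs are byte-level
deterministic under the seed.

The template has macro-chromosomes (default 2 × 40–80 kb at GC 0.40) and
micro-chromosomes (default 4 × 8–20 kb at GC 0.52), mirroring the
macro/micro size and GC contrast of avian genomes at desk scale. The
derived assembly cuts each chromosome into 2–5 fragments tiling it
completely, reverse-complements each with probability 0.3, joins 2
cross-chromosome fragment pairs with 100-N runs (chimeras), and plants
substitutions at rate 0.001. The `chicken-like` preset adds shuffled
decoy fragments (8 %) emulating unplaced content: per-base shuffling
preserves composition but destroys alignable homology, which the exact
k-mer anchor aligner (`anchor_align`, a seed-and-chain scorer over
31-mers) confirms empirically — decoys never reach the 0.5 ratio. The
`small` preset omits decoys, so on it a correct pipeline places 100 % of
bases. Truth alignments carry exact coordinates and model substitutions
only through the identity field; indels, rearrangement breakpoints
inside fragments, repeats and uneven coverage are *not* simulated, so
passing the suite demonstrates the bookkeeping and decision rules, not
robustness to noisy real alignments (which enter the pipeline through
whatever aligner produced them).

The planted-error QV fixture feeds the genome's own k-mers in as "read"
k-mers with `reliable_threshold=1`: genome-derived k-mers occur about
once each, so the default threshold of 2 — meant for multi-coverage read
sets — would empty the reliable set.

The corruption generator deletes the last `missing_count` chromosomes,
cuts each into 2–4 contigs and either appends them (100-N joints,
possibly inverted) to surviving host chromosomes or drops them into the
unplaced pool, recording the diaspora for provenance-set verification.

## Problem sizes in the test and acceptance suites

Bulk property suites (base conservation through build and correct, 200
seeds each) run on a `tiny` config (1 macro 3–6 kb + 2–3 micro 1–2 kb
chromosomes) so each fixture costs milliseconds; recovery suites use the
`small` preset (~170 kb genomes); the QV fixture is 100 kb with 10
substitutions. These sizes were chosen so the full suite runs in well
under a minute while every rule still has multiple chromosomes,
inversions, chimeras and gaps to act on.

## Known limitations

* Alignments are inputs; the package does not run an aligner, and the
  bundled anchor aligner is a fixture-scoring tool, not a substitute for
  blastn/minimap2 on real data.
* Chimera splitting happens only at N joints; a chimera fused without a
  joint is flagged but assigned whole, since no split coordinate is
  defensible.
* Hit re-attribution after a split assigns whole hits by majority
  overlap; a single HSP genuinely spanning a joint contributes its full
  weight to one side.
* `keep_fraction = 0.95` is an operational default, not an empirically
  fitted value; sensitivity to it should be checked on real data.
* Mitochondrial reconstruction from reads, Hi-C scaffolding, gap
  filling and polishing are out of scope.
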