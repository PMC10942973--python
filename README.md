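# refchrom

Template-guided chromosome building, assembly correction and QC metrics
for draft genome assemblies.

## The problem

Long-read assemblers and Hi-C scaffolders produce scaffolds, not
chromosomes. When a finished genome of a closely related individual or
breed exists (a *template*), scaffolds can be sorted into chromosomes by
homology: align every scaffold to the template, decide which chromosome
each one belongs to, orient and order the placed scaffolds along the
template, and concatenate them. The same machinery corrects an older
chromosome-level assembly against a newer template: chromosomes that map
cleanly are kept, mis-scaffolded ones are split back into contigs at the
N-gap joints that scaffolding introduced, and missing or mis-assembled
chromosomes are rebuilt from the split and unplaced contigs. This is the
procedure used to build indigenous-chicken genomes against the GRCg7b
chicken reference and to reconstruct the micro-chromosomes (chr29,
chr34–39) absent from the GRCg6a red-jungle-fowl assembly.

`refchrom` implements that procedure as a tested library and CLI,
together with the assembly QC metrics used to evaluate the results, and
a synthetic-genome generator with ground truth so the whole pipeline can
be exercised without real data or an external aligner.

## The rules at the core

**Assignment (ratio rule).** A scaffold *q* is mapped to template
chromosome *c* when

```
r(q, c) = mapped_length(q, c) / min(len(q), len(c)) > 0.5   (strict)
```

where `mapped_length` is the length of the union of *q*'s aligned query
intervals against *c* (overlapping local alignments counted once).
The chromosome with the largest ratio above the threshold wins; a
scaffold exceeding the threshold nowhere is *unplaced*.

**Orientation and order.** A placed scaffold takes the strand carrying
the majority of its aligned bases, and is ordered along the chromosome
by the aligned-length-weighted mean of its hit midpoints on the
template. Per chromosome, scaffolds are concatenated in that order with
500-N separators.

**Chimera splitting.** When parts of one scaffold map to different
chromosomes and the parts are joined by a run of Ns (scaffolding tools
bridge contigs with 100 Ns), the scaffold is a chimeric join: it is
split at the N run and each part is assigned independently. Conflicting
mappings *without* an N joint are flagged, not split.

**Correction.** An assembly chromosome is kept intact when ≥ 95 % of
its non-N bases align to its name-matched template chromosome and none
of its N-gap-delimited contigs is assigned to a different chromosome;
otherwise it is decomposed into contigs between the Ns, and missing or
mis-assembled chromosomes are rebuilt from the pooled split + unplaced
contigs by the same assign/orient/order/concatenate-by-500-N rules. Each
rebuilt chromosome is reported as a percentage of its template
counterpart's non-N length.

**QC metrics.** Contig/scaffold/chromosome N50; gap counts;
per-chromosome GC and non-N length ratio versus a reference; placement
rate (% of non-N bases assigned to chromosomes); and the k-mer pair
(k = 17, canonical):

```
QV = -10 log10(1 - (K_shared / K_total)^(1/k))        k-mer QV
completeness = |reliable read k-mers in assembly| / |reliable read k-mers|
accuracy = 1 - 10^(-QV/10)
```

where `K_total` counts assembly k-mers with multiplicity and `K_shared`
those supported by reliable (count ≥ 2 by default) read k-mers.

## Worked example

```
$ refchrom simulate --seed 1 --preset small --out-dir demo
wrote small fixture (seed 1) to demo

$ refchrom build --assembly demo/assembly.fasta --template demo/template.fasta \
    --alignments demo/truth.paf --dialect paf --out-prefix demo/out --verbose
warning: scaffold_1 split_chimera
warning: scaffold_2 split_chimera
built 6 chromosomes, 0 unplaced

$ refchrom metrics --assembly demo/out.chromosomes.fasta \
    --reference demo/template.fasta --out demo/metrics.tsv
placement_rate	100.00
contig_n50	11297
```

The simulated genome has 2 macro- and 4 micro-chromosomes; the derived
assembly fragments them, inverts some fragments and joins two pairs of
fragments from different chromosomes with 100-N runs. The `build` step
recovers all six chromosomes, splits both chimeric scaffolds at their
joints (the warnings name them), and places every base, hence the
placement rate of 100 %. `demo/out.placements.tsv` records each verdict:

```
query	seg_start	seg_end	chromosome	ratio	orientation	order_key	flags
scaffold_1	0	6496	chr4	1.0	+	11591.0	split_chimera
scaffold_1	6596	9646	chr5	1.0	+	7100.0	split_chimera
scaffold_3	0	6441	chr1	1.0	+	3220.5	
```

`scaffold_1` was split at its N joint (bases 6496–6596) into a chr4 part
and a chr5 part, each with assignment ratio 1.0; `order_key` is the
scaffold's position on the template used for ordering. `demo/out.agp`
holds the same structure as AGP v2.1 component and 500-N gap lines.

The `correct` subcommand runs the keep/decompose/rebuild pass and
writes a per-rebuilt-chromosome report (template non-N length,
contributing contigs per source, rebuilt non-N length, percentage), and
`kmerqv` computes the QV/completeness pair alone.

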