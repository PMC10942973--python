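"""Correction of a chromosome-level assembly against a template genome.

Given an existing assembly (chromosomes plus an unplaced-contig pool)
and alignments of all of it against a template genome, each assembly
chromosome is either

* **kept** intact, when essentially all of its non-N bases align to its
  name-matched template chromosome (``keep_fraction``, default 0.95), or
* **decomposed** into the contigs between its N-gap joints, when its
  pieces map to different template chromosomes (mis-scaffolding) or it
  has no matching template counterpart.

The split contigs, pooled with the pre-existing unplaced contigs, are
then sorted onto the template chromosomes that are *not* kept — the
missing or mis-assembled ones — using the same ratio rule as the
builder, oriented and ordered along the template, and concatenated with
500-N gaps into rebuilt chromosomes.  A report compares each rebuilt
chromosome's non-N length with its template counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from refchrom.chrom_builder import (
    ChromosomeBuild,
    PlacedSegment,
    UNPLACED,
    _attribute_hits_to_segments,
    _group_by_target,
    assign_scaffold,
    merge_intervals,
    orient_and_key,
    split_at_n_runs,
)
from refchrom.io_formats import AlignmentHit, SequenceRecord


@dataclass(frozen=True)
class ContigSpan:
    """A gap-free-enough piece of a parent sequence (no N run >= threshold)."""

    parent_id: str
    span: tuple[int, int]
    seq: str

    @property
    def contig_id(self) -> str:
        return f"{self.parent_id}:{self.span[0]}-{self.span[1]}"

    @property
    def nonn_length(self) -> int:
        return len(self.seq) - self.seq.count("N") - self.seq.count("n")


@dataclass
class CorrectionPlan:
    kept: list[str] = field(default_factory=list)
    decomposed: dict[str, list[ContigSpan]] = field(default_factory=dict)
    rebuilt: dict[str, ChromosomeBuild] = field(default_factory=dict)
    contig_provenance: dict[str, tuple[str, tuple[int, int]]] = field(
        default_factory=dict
    )
    warnings: list[str] = field(default_factory=list)


def percentage_vs_template(rebuilt_nonn_len: int, template_nonn_len: int) -> float:
    """100 * rebuilt / template, rounded half-up to 2 decimals; may exceed 100."""
    if template_nonn_len <= 0:
        raise ValueError("template non-N length must be positive")
    pct = Decimal(100 * rebuilt_nonn_len) / Decimal(template_nonn_len)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_chromosomes(
    assembly: Sequence[SequenceRecord],
    template: Sequence[SequenceRecord],
    hits: Sequence[AlignmentHit],
    keep_fraction: float = 0.95,
    min_gap: int = 10,
    name_map: Mapping[str, str] | None = None,
) -> CorrectionPlan:
    """Sort assembly chromosomes into KEPT and DECOMPOSED.

    A chromosome is kept when (a) >= ``keep_fraction`` of its non-N
    bases are covered by merged alignments to its name-matched template
    chromosome (identity naming unless ``name_map`` says otherwise) and
    (b) none of its N-gap-delimited contigs is assigned by the ratio
    rule to a *different* template chromosome — foreign contigs indicate
    mis-scaffolding no matter how small they are relative to the host.
    Everything else is split between its N runs into contigs.
    """

    def merged_coverage(hs: list[AlignmentHit]) -> int:
        if not hs:
            return 0
        return sum(e - s for s, e in merge_intervals((h.q_start, h.q_end) for h in hs))

    template_ids = {rec.id for rec in template}
    template_lengths = {rec.id: len(rec.seq) for rec in template}
    per_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        per_query.setdefault(h.query_id, []).append(h)

    plan = CorrectionPlan()
    for rec in assembly:
        counterpart = (name_map or {}).get(rec.id, rec.id)
        own_hits = [
            h for h in per_query.get(rec.id, []) if h.target_id == counterpart
        ]
        if counterpart not in template_ids:
            if not per_query.get(rec.id):
                plan.warnings.append(
                    f"{rec.id}: no template counterpart and no alignments; decomposing"
                )
            coverage = 0.0
        else:
            coverage = min(1.0, merged_coverage(own_hits) / max(1, rec.nonn_length))
        has_foreign_contig = False
        if coverage >= keep_fraction:
            spans = [span for span, _ in split_at_n_runs(rec, min_gap)]
            attributed = _attribute_hits_to_segments(per_query.get(rec.id, []), spans)
            for span, seg_hits in zip(spans, attributed):
                d = assign_scaffold(
                    _group_by_target(seg_hits),
                    span[1] - span[0],
                    template_lengths,
                    query_id=rec.id,
                    segment_span=span,
                )
                if d.chromosome_id not in (UNPLACED, counterpart):
                    has_foreign_contig = True
                    break
        if coverage >= keep_fraction and not has_foreign_contig:
            plan.kept.append(rec.id)
        else:
            contigs = [
                ContigSpan(rec.id, span, seq)
                for span, seq in split_at_n_runs(rec, min_gap)
            ]
            plan.decomposed[rec.id] = contigs
            for c in contigs:
                plan.contig_provenance[c.contig_id] = (rec.id, c.span)
    return plan


def rebuild_missing(
    contigs: Sequence[ContigSpan],
    contig_hits: Mapping[str, Sequence[AlignmentHit]],
    template_lengths: Mapping[str, int],
    template_nonn_lengths: Mapping[str, int],
    gap: int = 500,
    threshold: float = 0.5,
    allowed_targets: set[str] | None = None,
) -> tuple[dict[str, ChromosomeBuild], list[ContigSpan], pd.DataFrame]:
    """Assign contigs to (missing/mis-assembled) template chromosomes.

    Each contig runs through the builder's ratio rule against
    ``allowed_targets`` (default: all template chromosomes), is oriented
    by majority strand and ordered by its weighted target midpoint;
    per-chromosome contigs are concatenated with ``gap`` Ns.  Returns
    the builds, the contigs left unassigned, and a report with one row
    per rebuilt chromosome: template non-N length, contributing contig
    count and per-source breakdown, rebuilt non-N length, and the
    rebuilt/template percentage.
    """
    targets = set(allowed_targets) if allowed_targets is not None else set(
        template_lengths
    )
    per_chrom: dict[str, list[tuple[float, ContigSpan, str]]] = {}
    unassigned: list[ContigSpan] = []
    for contig in contigs:
        hits = [
            h
            for h in contig_hits.get(contig.contig_id, [])
            if h.target_id in targets
        ]
        decision = assign_scaffold(
            _group_by_target(hits),
            len(contig.seq),
            template_lengths,
            threshold,
            query_id=contig.contig_id,
        )
        if decision.chromosome_id == UNPLACED:
            unassigned.append(contig)
        else:
            per_chrom.setdefault(decision.chromosome_id, []).append(
                (decision.order_key, contig, decision.orientation)
            )

    builds: dict[str, ChromosomeBuild] = {}
    rows = []
    for chrom in sorted(per_chrom):
        entries = sorted(per_chrom[chrom], key=lambda t: (t[0], t[1].contig_id))
        segments = [
            PlacedSegment(c.contig_id, (0, len(c.seq)), orient, key)
            for key, c, orient in entries
        ]
        builds[chrom] = ChromosomeBuild(chrom, segments, inter_segment_gap=gap)
        rebuilt_nonn = sum(c.nonn_length for _, c, _ in entries)
        sources = sorted({c.parent_id for _, c, _ in entries})
        breakdown = ";".join(
            f"{src}:{sum(1 for _, c, _ in entries if c.parent_id == src)}"
            for src in sources
        )
        rows.append(
            {
                "chromosome": chrom,
                "template_nonn_len": template_nonn_lengths[chrom],
                "n_contigs": len(entries),
                "contig_sources": breakdown,
                "rebuilt_nonn_len": rebuilt_nonn,
                "percentage": percentage_vs_template(
                    rebuilt_nonn, template_nonn_lengths[chrom]
                ),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "template_nonn_len",
            "n_contigs",
            "contig_sources",
            "rebuilt_nonn_len",
            "percentage",
        ],
    )
    return builds, unassigned, report


def correct_assembly(
    assembly: Sequence[SequenceRecord],
    unplaced: Sequence[SequenceRecord],
    template: Sequence[SequenceRecord],
    hits: Sequence[AlignmentHit],
    keep_fraction: float = 0.95,
    min_gap: int = 10,
    gap: int = 500,
    threshold: float = 0.5,
    name_map: Mapping[str, str] | None = None,
) -> tuple[CorrectionPlan, list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Full correction pass.

    Returns ``(plan, corrected_records, remaining_unplaced, report)``;
    ``corrected_records`` holds the kept chromosomes byte-identical plus
    the rebuilt chromosomes (named by template chromosome).
    """
    by_id = {rec.id: rec for rec in assembly}
    plan = classify_chromosomes(
        assembly, template, hits, keep_fraction, min_gap, name_map
    )

    # pool: contigs of decomposed chromosomes + contigs of unplaced records
    pool: list[ContigSpan] = []
    for contigs in plan.decomposed.values():
        pool.extend(contigs)
    for rec in unplaced:
        for span, seq in split_at_n_runs(rec, min_gap):
            c = ContigSpan(rec.id, span, seq)
            pool.append(c)
            plan.contig_provenance[c.contig_id] = (rec.id, c.span)

    # re-attribute parent-level hits onto contigs with rebased coordinates
    per_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        per_query.setdefault(h.query_id, []).append(h)
    by_parent: dict[str, list[ContigSpan]] = {}
    for c in pool:
        by_parent.setdefault(c.parent_id, []).append(c)
    contig_hits: dict[str, list[AlignmentHit]] = {}
    for parent, contigs in by_parent.items():
        contigs = sorted(contigs, key=lambda c: c.span)
        spans = [c.span for c in contigs]
        attributed = _attribute_hits_to_segments(per_query.get(parent, []), spans)
        for contig, seg_hits in zip(contigs, attributed):
            off = contig.span[0]
            contig_hits[contig.contig_id] = [
                AlignmentHit(
                    contig.contig_id,
                    h.target_id,
                    h.q_start - off,
                    h.q_end - off,
                    h.t_start,
                    h.t_end,
                    h.strand,
                    h.identity,
                )
                for h in seg_hits
            ]

    template_lengths = {rec.id: len(rec.seq) for rec in template}
    template_nonn = {rec.id: rec.nonn_length for rec in template}
    kept_targets = {(name_map or {}).get(k, k) for k in plan.kept}
    builds, unassigned, report = rebuild_missing(
        pool,
        contig_hits,
        template_lengths,
        template_nonn,
        gap=gap,
        threshold=threshold,
        allowed_targets=set(template_lengths) - kept_targets,
    )
    plan.rebuilt = builds

    contig_seqs = {c.contig_id: c.seq for c in pool}
    corrected: list[SequenceRecord] = [by_id[k] for k in plan.kept]
    for chrom, build in builds.items():
        corrected.append(SequenceRecord(chrom, build.render(contig_seqs)))
    parent_lens = {rec.id: len(rec.seq) for rec in list(assembly) + list(unplaced)}
    remaining = [
        SequenceRecord(
            c.parent_id if c.span == (0, parent_lens.get(c.parent_id, -1)) else c.contig_id,
            c.seq,
        )
        for c in unassigned
    ]
    return plan, corrected, remaining, report
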