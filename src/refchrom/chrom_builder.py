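"""Template-guided chromosome building.

A scaffold is assigned to the template chromosome for which the ratio

    mapped_length / min(scaffold_length, chromosome_length)

is largest, provided that ratio exceeds a strict threshold (default
0.5); otherwise it is left unplaced.  "Mapped length" is the length of
the *union* of the scaffold's query intervals against that chromosome,
so overlapping local alignments are counted once.

Scaffolds whose N-gap-separated parts map to different chromosomes are
chimeric joins from scaffolding and are split at those N runs, each part
being assigned independently.  Placed scaffolds are oriented by the
strand carrying the majority of aligned bases and ordered along the
template by the aligned-length-weighted mean of their hit midpoints,
then concatenated with a fixed run of Ns (default 500) per chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from refchrom.io_formats import AlignmentHit, RefchromError, SequenceRecord

#: Sentinel chromosome id for scaffolds that fail the assignment rule.
UNPLACED = "unplaced"

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv", "TGCANYRSWMKVHDBtgcanyrswmkvhdb"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case (involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlacementDecision:
    """Verdict for one query scaffold or scaffold segment."""

    query_id: str
    segment_span: tuple[int, int]  # 0-based half-open on the original scaffold
    chromosome_id: str  # UNPLACED when the ratio rule fails
    ratio: float
    orientation: str = "+"
    order_key: float = 0.0
    evidence: tuple[int, ...] = ()  # indices of contributing hits
    flags: tuple[str, ...] = ()

    @property
    def placed(self) -> bool:
        return self.chromosome_id != UNPLACED

    @property
    def segment_length(self) -> int:
        return self.segment_span[1] - self.segment_span[0]


@dataclass(frozen=True)
class PlacedSegment:
    query_id: str
    span: tuple[int, int]
    orientation: str
    order_key: float = 0.0


@dataclass
class ChromosomeBuild:
    """An ordered, oriented list of placed segments for one chromosome."""

    chromosome_id: str
    segments: list[PlacedSegment]
    inter_segment_gap: int = 500

    @property
    def rendered_length(self) -> int:
        total = sum(s.span[1] - s.span[0] for s in self.segments)
        return total + self.inter_segment_gap * max(0, len(self.segments) - 1)

    def render(self, sequences: Mapping[str, str]) -> str:
        """Concatenate segments ('-' reverse-complemented) with N gaps."""
        parts: list[str] = []
        for seg in self.segments:
            sub = sequences[seg.query_id][seg.span[0] : seg.span[1]]
            parts.append(reverse_complement(sub) if seg.orientation == "-" else sub)
        return ("N" * self.inter_segment_gap).join(parts)


# ---------------------------------------------------------------------------
# Interval arithmetic and the ratio rule
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge half-open intervals; touching intervals merge.

    Output is sorted, pairwise disjoint and non-touching; its union
    equals the union of the input.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if start >= end:
            raise ValueError(f"invalid interval [{start},{end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def mapped_ratio(
    hits: Sequence[AlignmentHit], query_len: int, target_len: int
) -> float:
    """Merged query coverage over min(query_len, target_len), capped at 1."""
    if query_len <= 0 or target_len <= 0:
        raise ValueError("query_len and target_len must be positive")
    if not hits:
        return 0.0
    merged = merge_intervals((h.q_start, h.q_end) for h in hits)
    covered = sum(e - s for s, e in merged)
    return min(1.0, covered / min(query_len, target_len))


def assign_scaffold(
    per_chromosome_hits: Mapping[str, Sequence[AlignmentHit]],
    query_len: int,
    template_lengths: Mapping[str, int],
    threshold: float = 0.5,
    query_id: str = "",
    segment_span: tuple[int, int] | None = None,
) -> PlacementDecision:
    """Apply the ratio rule across candidate chromosomes.

    The winner must have ratio strictly greater than ``threshold``; ties
    on ratio break by larger total aligned bases, then lexicographically
    smaller chromosome id, so output is deterministic.
    """
    span = segment_span if segment_span is not None else (0, query_len)
    scored: list[tuple[float, int, str]] = []
    for chrom, hits in per_chromosome_hits.items():
        if chrom not in template_lengths:
            raise RefchromError(f"alignment target {chrom!r} not in template")
        r = mapped_ratio(hits, query_len, template_lengths[chrom])
        scored.append((r, sum(h.aligned_bases for h in hits), chrom))
    if not scored:
        return PlacementDecision(query_id, span, UNPLACED, 0.0)
    best_ratio, best_bases, best_chrom = min(
        scored, key=lambda t: (-t[0], -t[1], t[2])
    )
    if best_ratio <= threshold:
        return PlacementDecision(query_id, span, UNPLACED, best_ratio)
    orientation, order_key = orient_and_key(per_chromosome_hits[best_chrom])
    flags = ()
    runners_up = [c for r, _, c in scored if r > threshold and c != best_chrom]
    if runners_up:
        flags = ("multi_chromosome_ratio",)
    return PlacementDecision(
        query_id, span, best_chrom, best_ratio, orientation, order_key, flags=flags
    )


def orient_and_key(hits: Sequence[AlignmentHit]) -> tuple[str, float]:
    """Majority-strand orientation and weighted-mean target midpoint.

    Orientation is the strand carrying more aligned bases (tie -> '+');
    the order key is sum(aligned_bases * target_midpoint) / sum(aligned_bases).
    """
    if not hits:
        raise RefchromError("orient_and_key requires at least one hit")
    plus = sum(h.aligned_bases for h in hits if h.strand == "+")
    minus = sum(h.aligned_bases for h in hits if h.strand == "-")
    orientation = "-" if minus > plus else "+"
    total = plus + minus
    order_key = sum(h.aligned_bases * h.t_mid for h in hits) / total
    return orientation, order_key


# ---------------------------------------------------------------------------
# N-run splitting and chimera handling
# ---------------------------------------------------------------------------


def split_at_n_runs(
    record: SequenceRecord, min_gap: int = 10
) -> list[tuple[tuple[int, int], str]]:
    """Cut a sequence at N runs of length >= ``min_gap``.

    Returns ``(span, subsequence)`` pairs, spans 0-based half-open on the
    parent.  Shorter N runs stay inside their segment, so concatenating
    the segments and the qualifying N runs reconstructs the parent.
    An all-N sequence yields an empty list.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    segments: list[tuple[tuple[int, int], str]] = []
    pos = 0
    for m in re.finditer(f"[Nn]{{{min_gap},}}", record.seq):
        if m.start() > pos:
            segments.append(((pos, m.start()), record.seq[pos : m.start()]))
        pos = m.end()
    if pos < len(record.seq):
        segments.append(((pos, len(record.seq)), record.seq[pos:]))
    return segments


def gap_runs(record: SequenceRecord, min_gap: int = 10) -> list[tuple[int, int]]:
    """Spans of the qualifying N runs (the complement of split_at_n_runs)."""
    return [
        (m.start(), m.end())
        for m in re.finditer(f"[Nn]{{{min_gap},}}", record.seq)
    ]


def _attribute_hits_to_segments(
    hits: Sequence[AlignmentHit], spans: Sequence[tuple[int, int]]
) -> list[list[AlignmentHit]]:
    """Assign each hit to the segment holding the majority of its query interval.

    An exact 50/50 straddle goes to the left segment.  The winning
    segment receives the hit with its query interval clipped to the
    segment (target interval left untouched: only its midpoint is used
    downstream, for ordering).
    """
    per_segment: list[list[AlignmentHit]] = [[] for _ in spans]
    for h in hits:
        overlaps = [
            max(0, min(h.q_end, e) - max(h.q_start, s)) for s, e in spans
        ]
        best = max(range(len(spans)), key=lambda i: (overlaps[i], -i))
        if overlaps[best] == 0:
            continue  # hit lies entirely inside a gap run
        s, e = spans[best]
        qs, qe = max(h.q_start, s), min(h.q_end, e)
        per_segment[best].append(replace(h, q_start=qs, q_end=qe))
    return per_segment


def _group_by_target(
    hits: Sequence[AlignmentHit],
) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.target_id, []).append(h)
    return grouped


def detect_and_split_chimeras(
    record: SequenceRecord,
    hits: Sequence[AlignmentHit],
    template_lengths: Mapping[str, int],
    min_gap: int = 10,
    threshold: float = 0.5,
) -> list[PlacementDecision]:
    """Place one scaffold, splitting it at N joints if chimeric.

    The scaffold is decomposed at its qualifying N runs; hits are
    re-attributed to segments and each segment assigned independently.
    If two or more segments land on different chromosomes the scaffold
    is a chimeric join and the per-segment decisions are returned;
    otherwise the whole-scaffold decision stands.  Conflicting ratios on
    a scaffold *without* an N joint are flagged, not split.
    """
    whole = assign_scaffold(
        _group_by_target(hits),
        len(record.seq),
        template_lengths,
        threshold,
        query_id=record.id,
    )
    if whole.placed and "multi_chromosome_ratio" in whole.flags:
        whole = replace(whole, flags=whole.flags + ("possible_chimera_no_joint",))

    spans = [span for span, _ in split_at_n_runs(record, min_gap)]
    if len(spans) < 2:
        return [whole]

    per_segment_hits = _attribute_hits_to_segments(hits, spans)
    decisions: list[PlacementDecision] = []
    for span, seg_hits in zip(spans, per_segment_hits):
        seg_len = span[1] - span[0]
        d = assign_scaffold(
            _group_by_target(seg_hits),
            seg_len,
            template_lengths,
            threshold,
            query_id=record.id,
            segment_span=span,
        )
        decisions.append(d)
    placed_chroms = {d.chromosome_id for d in decisions if d.placed}
    if len(placed_chroms) >= 2:
        return [replace(d, flags=d.flags + ("split_chimera",)) for d in decisions]
    return [whole]


# ---------------------------------------------------------------------------
# Rendering chromosomes
# ---------------------------------------------------------------------------


def build_chromosomes(
    decisions: Sequence[PlacementDecision],
    scaffolds: Sequence[SequenceRecord],
    gap: int = 500,
) -> tuple[list[ChromosomeBuild], list[SequenceRecord]]:
    """Group placed decisions per chromosome, order, and collect unplaced.

    Segments are sorted by order key (ties by query id then span for
    determinism); minus-orientation segments are reverse-complemented at
    render time.  Unplaced whole scaffolds pass through unchanged;
    unplaced *segments* of split scaffolds are emitted as
    ``id:start-end`` records.
    """
    by_id = {rec.id: rec for rec in scaffolds}
    claimed: dict[str, list[tuple[int, int]]] = {}
    for d in decisions:
        if d.query_id not in by_id:
            raise RefchromError(f"decision references unknown scaffold {d.query_id!r}")
        spans = claimed.setdefault(d.query_id, [])
        for s, e in spans:
            if max(s, d.segment_span[0]) < min(e, d.segment_span[1]):
                raise RefchromError(
                    f"overlapping segment claims on scaffold {d.query_id!r}"
                )
        spans.append(d.segment_span)

    per_chrom: dict[str, list[PlacementDecision]] = {}
    unplaced: list[SequenceRecord] = []
    for d in decisions:
        if d.placed:
            per_chrom.setdefault(d.chromosome_id, []).append(d)
        else:
            rec = by_id[d.query_id]
            if d.segment_span == (0, len(rec.seq)):
                unplaced.append(rec)
            else:
                s, e = d.segment_span
                unplaced.append(
                    SequenceRecord(f"{rec.id}:{s}-{e}", rec.seq[s:e])
                )
    builds: list[ChromosomeBuild] = []
    for chrom in sorted(per_chrom):
        ds = sorted(
            per_chrom[chrom], key=lambda d: (d.order_key, d.query_id, d.segment_span)
        )
        builds.append(
            ChromosomeBuild(
                chromosome_id=chrom,
                segments=[
                    PlacedSegment(d.query_id, d.segment_span, d.orientation, d.order_key)
                    for d in ds
                ],
                inter_segment_gap=gap,
            )
        )
    return builds, unplaced


def place_assembly(
    scaffolds: Sequence[SequenceRecord],
    hits: Sequence[AlignmentHit],
    template_lengths: Mapping[str, int],
    gap: int = 500,
    min_gap: int = 10,
    threshold: float = 0.5,
    min_identity: float = 0.0,
) -> tuple[list[PlacementDecision], list[ChromosomeBuild], list[SequenceRecord]]:
    """End-to-end placement: decide every scaffold, then build chromosomes."""
    known = {rec.id for rec in scaffolds}
    per_query: dict[str, list[AlignmentHit]] = {rec.id: [] for rec in scaffolds}
    for h in hits:
        if h.query_id not in known:
            raise RefchromError(f"alignment references unknown scaffold {h.query_id!r}")
        if h.identity >= min_identity:
            per_query[h.query_id].append(h)
    decisions: list[PlacementDecision] = []
    for rec in scaffolds:
        decisions.extend(
            detect_and_split_chimeras(
                rec, per_query[rec.id], template_lengths, min_gap, threshold
            )
        )
    builds, unplaced = build_chromosomes(decisions, scaffolds, gap)
    return decisions, builds, unplaced
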