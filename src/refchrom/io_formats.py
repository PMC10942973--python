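"""Readers and writers for the formats the pipeline touches.

FASTA (via Biopython), BLAST tabular ``-outfmt 6``, PAF, AGP v2.1,
headered TSV reports and a two-column k-mer count table.

Coordinate conventions
----------------------
Every :class:`AlignmentHit` held in memory uses 0-based half-open
intervals on the *forward* strand of both query and target, with a
separate ``strand`` field.  BLAST6 (1-based inclusive, minus-strand hits
encoded by ``sstart > send``) is normalized on read; PAF already matches
the internal convention and its strand column is trusted as-is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO


class RefchromError(Exception):
    """Base class for data/consistency errors raised by this package."""


class FormatError(RefchromError):
    """A file does not conform to its declared format."""


_IUPAC_DNA = set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence: scaffold, contig or template chromosome."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")
        if len(self.seq) < 1:
            raise FormatError(f"empty sequence body for record {self.id!r}")
        bad = set(self.seq) - _IUPAC_DNA
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def nonn_length(self) -> int:
        """Number of bases that are not N/n."""
        return len(self.seq) - self.seq.count("N") - self.seq.count("n")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a template chromosome.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; ``aligned_bases`` is the query-interval length.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise FormatError(
                f"bad query interval [{self.q_start},{self.q_end}) for {self.query_id}"
            )
        if not (0 <= self.t_start < self.t_end):
            raise FormatError(
                f"bad target interval [{self.t_start},{self.t_end}) for {self.query_id}"
            )
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def aligned_bases(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_mid(self) -> float:
        return (self.t_start + self.t_end) / 2.0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` values.

    Case is preserved.  Duplicate ids, empty bodies and non-FASTA
    content raise :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    with path.open() as fh:
        text_head = fh.read(1)
    if text_head not in (">", ""):
        raise FormatError(f"{path}: not FASTA (first character {text_head!r})")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence body for {rec.id!r}")
        desc = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records wrapped at ``wrap`` columns (read∘write∘read identity)."""
    if wrap < 1:
        raise ValueError("wrap width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Alignments: BLAST outfmt-6 and PAF
# ---------------------------------------------------------------------------


def _parse_int(token: str, path: Path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric coordinate {token!r}") from None


def read_alignments(path: str | Path, dialect: str) -> list[AlignmentHit]:
    """Read alignments in ``blast6`` or ``paf`` dialect, normalized.

    BLAST6: 12 tab columns, 1-based inclusive; a subject interval with
    start > end encodes a minus-strand hit and is swapped.  PAF: >= 12
    columns, already 0-based half-open with an explicit strand column.
    """
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "blast6":
                if len(cols) != 12:
                    raise FormatError(
                        f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                    )
                qid, tid = cols[0], cols[1]
                ident = float(cols[2]) / 100.0
                qs = _parse_int(cols[6], path, lineno) - 1
                qe = _parse_int(cols[7], path, lineno)
                ss = _parse_int(cols[8], path, lineno)
                se = _parse_int(cols[9], path, lineno)
                if ss <= se:
                    strand, ts, te = "+", ss - 1, se
                else:
                    strand, ts, te = "-", se - 1, ss
            else:
                if len(cols) < 12:
                    raise FormatError(
                        f"{path}:{lineno}: expected >=12 columns, got {len(cols)}"
                    )
                qid, tid = cols[0], cols[5]
                qs = _parse_int(cols[2], path, lineno)
                qe = _parse_int(cols[3], path, lineno)
                strand = cols[4]
                ts = _parse_int(cols[7], path, lineno)
                te = _parse_int(cols[8], path, lineno)
                nmatch = _parse_int(cols[9], path, lineno)
                alnlen = _parse_int(cols[10], path, lineno)
                ident = nmatch / alnlen if alnlen else 1.0
            if qs >= qe:
                raise FormatError(
                    f"{path}:{lineno}: empty query interval after normalization"
                )
            try:
                hits.append(
                    AlignmentHit(qid, tid, qs, qe, ts, te, strand, round(ident, 6))
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_alignments(
    hits: Sequence[AlignmentHit],
    path: str | Path,
    dialect: str,
    query_lengths: dict[str, int] | None = None,
    target_lengths: dict[str, int] | None = None,
) -> None:
    """Render hits as BLAST6 or PAF lines (PAF needs sequence lengths)."""
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    with open(path, "w") as fh:
        for h in hits:
            if dialect == "blast6":
                length = h.aligned_bases
                mismatch = round(length * (1.0 - h.identity))
                if h.strand == "+":
                    ss, se = h.t_start + 1, h.t_end
                else:
                    ss, se = h.t_end, h.t_start + 1
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            h.query_id,
                            h.target_id,
                            f"{h.identity * 100:.3f}",
                            length,
                            mismatch,
                            0,
                            h.q_start + 1,
                            h.q_end,
                            ss,
                            se,
                            "0.0",
                            f"{2 * length}",
                        )
                    )
                    + "\n"
                )
            else:
                if query_lengths is None or target_lengths is None:
                    raise ValueError("PAF output requires query and target lengths")
                alnlen = h.aligned_bases
                nmatch = round(alnlen * h.identity)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            h.query_id,
                            query_lengths[h.query_id],
                            h.q_start,
                            h.q_end,
                            h.strand,
                            h.target_id,
                            target_lengths[h.target_id],
                            h.t_start,
                            h.t_end,
                            nmatch,
                            alnlen,
                            255,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------


def write_agp(builds, path: str | Path) -> None:
    """Write ChromosomeBuilds as AGP v2.1.

    One W line per placed component (1-based inclusive object and
    component coordinates) and one N gap line of the configured length
    between consecutive components; object coordinates tile
    ``[1, rendered_length]`` exactly.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for build in builds:
            pos = 0  # 0-based cursor on the object
            part = 0
            for i, seg in enumerate(build.segments):
                seg_len = seg.span[1] - seg.span[0]
                if seg_len <= 0:
                    raise RefchromError(
                        f"zero-length component {seg.query_id} in {build.chromosome_id}"
                    )
                if i > 0 and build.inter_segment_gap > 0:
                    part += 1
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                build.chromosome_id,
                                pos + 1,
                                pos + build.inter_segment_gap,
                                part,
                                "N",
                                build.inter_segment_gap,
                                "scaffold",
                                "yes",
                                "align_genus",
                            )
                        )
                        + "\n"
                    )
                    pos += build.inter_segment_gap
                part += 1
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            build.chromosome_id,
                            pos + 1,
                            pos + seg_len,
                            part,
                            "W",
                            seg.query_id,
                            seg.span[0] + 1,
                            seg.span[1],
                            seg.orientation,
                        )
                    )
                    + "\n"
                )
                pos += seg_len


# ---------------------------------------------------------------------------
# k-mer count table and TSV reports
# ---------------------------------------------------------------------------

_KMER_RE = re.compile(r"^[ACGT]+$")


def read_kmer_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``kmer<TAB>count`` table (canonical k-mers)."""
    path = Path(path)
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            kmer, count = cols[0].upper(), cols[1]
            if not _KMER_RE.match(kmer):
                raise FormatError(f"{path}:{lineno}: invalid k-mer {cols[0]!r}")
            counts[kmer] = counts.get(kmer, 0) + _parse_int(count, path, lineno)
    return counts


def write_kmer_table(counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for kmer in sorted(counts):
            fh.write(f"{kmer}\t{counts[kmer]}\n")
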