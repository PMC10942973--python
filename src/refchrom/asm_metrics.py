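"""Assembly QC metrics.

The N50 family (contig / scaffold / chromosome), gap counts, per-
chromosome GC content and non-N length ratios against a reference,
placement rate, and the k-mer based base-accuracy pair:

* **k-mer QV** — the log-scaled probability of a consensus error,
  estimated by comparing the assembly's k-mers (with multiplicity)
  against the set of *reliable* k-mers from accurate short reads.  With
  a fraction ``K_shared / K_total`` of assembly k-mers supported by the
  reads, the per-base survival is ``P = (K_shared/K_total)**(1/k)``, the
  error rate is ``E = 1 - P`` and ``QV = -10 * log10(E)``.
* **k-mer completeness** — the fraction of distinct reliable read
  k-mers that are also found in the assembly.

k-mers are canonical (lexicographic minimum of a k-mer and its reverse
complement) and counted exactly in a hash map; assemblies at the scales
this package targets are small enough that probabilistic counting would
buy nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from refchrom.chrom_builder import reverse_complement, split_at_n_runs
from refchrom.io_formats import SequenceRecord

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# k-mer containers
# ---------------------------------------------------------------------------


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(seqs: Iterable[str], k: int) -> dict[str, int]:
    """Exact canonical k-mer counts; windows with non-ACGT bases skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for seq in seqs:
        s = seq.upper()
        # restart the window after every ambiguous base
        for clean in _acgt_runs(s):
            for i in range(len(clean) - k + 1):
                km = canonical(clean[i : i + k])
                counts[km] = counts.get(km, 0) + 1
    return counts


def _acgt_runs(seq: str) -> Iterable[str]:
    start = None
    for i, c in enumerate(seq):
        if c in _ACGT:
            if start is None:
                start = i
        elif start is not None:
            yield seq[start:i]
            start = None
    if start is not None:
        yield seq[start:]


@dataclass
class KmerSet:
    """Canonical k-mer counts plus the reliability threshold for reads."""

    k: int = 17
    counts: dict[str, int] = field(default_factory=dict)
    reliable_threshold: int = 2

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], k: int = 17, reliable_threshold: int = 2
    ) -> "KmerSet":
        return cls(k=k, counts=count_kmers(seqs, k), reliable_threshold=reliable_threshold)

    @property
    def total(self) -> int:
        """Total k-mers with multiplicity."""
        return sum(self.counts.values())

    def reliable(self) -> set[str]:
        """Distinct k-mers at or above the reliability threshold."""
        return {km for km, c in self.counts.items() if c >= self.reliable_threshold}


# ---------------------------------------------------------------------------
# Length statistics
# ---------------------------------------------------------------------------


def nxx(lengths: Sequence[int], x: float = 50) -> int:
    """Nx statistic: smallest L with sum(lengths >= L) >= x% of the total."""
    if not lengths:
        raise ValueError("nxx of an empty length list")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    total = sum(lengths)
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum >= total * x / 100.0:
            return length
    return min(lengths)  # unreachable for valid x


def decompose_lengths(
    records: Sequence[SequenceRecord], min_gap: int = 10
) -> tuple[list[int], list[int], int]:
    """(contig lengths, scaffold lengths, gap count) at the N-run threshold."""
    contig_lengths: list[int] = []
    scaffold_lengths: list[int] = []
    n_gaps = 0
    for rec in records:
        scaffold_lengths.append(len(rec.seq))
        segs = split_at_n_runs(rec, min_gap)
        contig_lengths.extend(e - s for (s, e), _ in segs)
        # gap runs are the parts of the record not covered by segments
        covered = sum(e - s for (s, e), _ in segs)
        gap_bases = len(rec.seq) - covered
        if gap_bases:
            spans = [span for span, _ in segs]
            n_gaps += _count_gap_runs(len(rec.seq), spans)
    return contig_lengths, scaffold_lengths, n_gaps


def _count_gap_runs(total_len: int, seg_spans: list[tuple[int, int]]) -> int:
    if not seg_spans:
        return 1
    runs = 0
    if seg_spans[0][0] > 0:
        runs += 1
    for (s0, e0), (s1, e1) in zip(seg_spans, seg_spans[1:]):
        if s1 > e0:
            runs += 1
    if seg_spans[-1][1] < total_len:
        runs += 1
    return runs


def gc_content(seq: str) -> float | None:
    """GC percent over non-N bases; None for an all-N/ambiguous sequence.

    IUPAC ambiguity codes other than N are excluded from numerator and
    denominator alike.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return None
    return 100.0 * gc / denom


def length_ratio_table(
    assembly_chroms: Sequence[SequenceRecord],
    reference_chroms: Sequence[SequenceRecord],
    name_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome non-N length ratio (assembly / reference).

    Chromosomes present on only one side get a missing (NaN) ratio.
    """
    amap = {rec.id: rec for rec in assembly_chroms}
    rmap = {rec.id: rec for rec in reference_chroms}
    rename = name_map or {}
    rows = []
    ref_claimed: set[str] = set()
    for aid, arec in amap.items():
        rid = rename.get(aid, aid)
        rrec = rmap.get(rid)
        if rrec is not None:
            ref_claimed.add(rid)
        rows.append(
            {
                "chromosome": aid,
                "assembly_nonn_len": arec.nonn_length,
                "reference_nonn_len": rrec.nonn_length if rrec else None,
                "ratio": (
                    arec.nonn_length / rrec.nonn_length
                    if rrec and rrec.nonn_length
                    else float("nan")
                ),
                "gc_percent": gc_content(arec.seq),
            }
        )
    for rid, rrec in rmap.items():
        if rid not in ref_claimed:
            rows.append(
                {
                    "chromosome": rid,
                    "assembly_nonn_len": None,
                    "reference_nonn_len": rrec.nonn_length,
                    "ratio": float("nan"),
                    "gc_percent": None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "assembly_nonn_len",
            "reference_nonn_len",
            "ratio",
            "gc_percent",
        ],
    )


def placement_rate(
    chromosome_records: Sequence[SequenceRecord],
    unplaced_records: Sequence[SequenceRecord],
) -> float:
    """Percent of non-N bases assigned to chromosomes."""
    placed = sum(rec.nonn_length for rec in chromosome_records)
    loose = sum(rec.nonn_length for rec in unplaced_records)
    if placed + loose == 0:
        raise ValueError("no non-N bases in either input")
    return 100.0 * placed / (placed + loose)


# ---------------------------------------------------------------------------
# k-mer QV and completeness
# ---------------------------------------------------------------------------


def kmer_qv(
    assembly_kmers: KmerSet, read_kmers: KmerSet, cap: float = 99.0
) -> float:
    """k-mer QV of an assembly against reliable read k-mers.

    Returns ``cap`` (reported downstream as ">=cap") when every assembly
    k-mer is supported — the zero-error limit.
    """
    if assembly_kmers.k != read_kmers.k:
        raise ValueError("assembly and read k-mer sets must share k")
    k_total = assembly_kmers.total
    if k_total == 0:
        raise ValueError("assembly k-mer set is empty")
    reliable = read_kmers.reliable()
    k_shared = sum(
        c for km, c in assembly_kmers.counts.items() if km in reliable
    )
    if k_shared == k_total:
        return cap
    p = (k_shared / k_total) ** (1.0 / assembly_kmers.k)
    return -10.0 * math.log10(1.0 - p)


def kmer_completeness(read_kmers: KmerSet, assembly_kmers: KmerSet) -> float:
    """Percent of distinct reliable read k-mers found in the assembly."""
    if assembly_kmers.k != read_kmers.k:
        raise ValueError("assembly and read k-mer sets must share k")
    reliable = read_kmers.reliable()
    if not reliable:
        raise ValueError("no reliable read k-mers")
    present = sum(1 for km in reliable if km in assembly_kmers.counts)
    return 100.0 * present / len(reliable)


def qv_to_accuracy(qv: float) -> float:
    """Consensus base accuracy (percent) implied by a QV."""
    if qv < 0:
        raise ValueError("QV must be non-negative")
    return 100.0 * (1.0 - 10.0 ** (-qv / 10.0))


def accuracy_to_qv(accuracy_percent: float) -> float:
    """Inverse of :func:`qv_to_accuracy`."""
    if not 0 <= accuracy_percent < 100:
        raise ValueError("accuracy must be in [0, 100)")
    return -10.0 * math.log10(1.0 - accuracy_percent / 100.0)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Table-style QC summary for one assembly."""

    contig_n50: int
    scaffold_n50: int | None
    chromosome_n50: int | None
    n_gaps: int
    total_len: int
    total_nonn_len: int
    per_chromosome: pd.DataFrame
    placement_rate: float | None = None
    kmer_qv: float | None = None
    kmer_qv_capped: bool = False
    kmer_completeness: float | None = None

    def to_frame(self) -> pd.DataFrame:
        qv = self.kmer_qv
        rows = {
            "contig_n50": self.contig_n50,
            "scaffold_n50": self.scaffold_n50,
            "chromosome_n50": self.chromosome_n50,
            "n_gaps": self.n_gaps,
            "total_len": self.total_len,
            "total_nonn_len": self.total_nonn_len,
            "placement_rate": self.placement_rate,
            "kmer_qv": (f">={qv:g}" if self.kmer_qv_capped and qv is not None else qv),
            "kmer_completeness": self.kmer_completeness,
        }
        return pd.DataFrame(
            [{"metric": k, "value": v} for k, v in rows.items() if v is not None]
        )


def compute_metrics(
    records: Sequence[SequenceRecord],
    unplaced: Sequence[SequenceRecord] = (),
    reference: Sequence[SequenceRecord] | None = None,
    read_kmers: KmerSet | None = None,
    k: int = 17,
    min_gap: int = 10,
    level: str = "chromosome",
    qv_cap: float = 99.0,
) -> MetricsReport:
    """Compute the full QC summary for one assembly.

    ``level`` says what the input records are: ``"chromosome"`` fills
    both the scaffold and chromosome N50 slots from the record lengths,
    ``"scaffold"`` leaves chromosome N50 empty.
    """
    if level not in ("chromosome", "scaffold"):
        raise ValueError(f"unknown level {level!r}")
    contig_lengths, record_lengths, n_gaps = decompose_lengths(records, min_gap)
    if not contig_lengths:
        raise ValueError("assembly has no non-gap sequence")
    per_chrom = length_ratio_table(records, reference or [])
    rate = None
    if unplaced or level == "chromosome":
        try:
            rate = placement_rate(records, unplaced)
        except ValueError:
            rate = None
    qv = comp = None
    capped = False
    if read_kmers is not None:
        asm_kmers = KmerSet.from_sequences(
            (rec.seq for rec in list(records) + list(unplaced)), k=read_kmers.k
        )
        qv = kmer_qv(asm_kmers, read_kmers, cap=qv_cap)
        capped = qv == qv_cap
        comp = kmer_completeness(read_kmers, asm_kmers)
    return MetricsReport(
        contig_n50=nxx(contig_lengths),
        scaffold_n50=nxx(record_lengths),
        chromosome_n50=nxx(record_lengths) if level == "chromosome" else None,
        n_gaps=n_gaps,
        total_len=sum(record_lengths) + sum(len(r.seq) for r in unplaced),
        total_nonn_len=sum(r.nonn_length for r in list(records) + list(unplaced)),
        per_chromosome=per_chrom,
        placement_rate=rate,
        kmer_qv=qv,
        kmer_qv_capped=capped,
        kmer_completeness=comp,
    )
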