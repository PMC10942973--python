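"""Synthetic genomes with ground truth for exercising the pipeline.

The generator emulates the structure of an avian genome assembly
project: a template genome with a few long, GC-poorer macro-chromosomes
and many short, GC-richer micro-chromosomes; a draft "assembly" derived
from it by fragmenting each chromosome, inverting some fragments,
joining fragments of *different* chromosomes with 100-N runs (chimeric
scaffolds, as scaffolding tools occasionally produce), emitting some
fragments as base-shuffled decoys with no template homology (unplaced
content), and planting random substitutions.  A manifest records every
operation, so truth-derived alignment records can stand in for a real
aligner and every pipeline verdict can be checked exactly.

A single integer seed drives one explicit PRNG threaded through all
generators; outputs are byte-level deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from refchrom.chrom_builder import reverse_complement
from refchrom.io_formats import AlignmentHit, SequenceRecord

_BASES = np.array(list("ACGT"))


class FixtureConfigError(ValueError):
    """An impossible fixture configuration."""


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic genome.

    Lengths are desk-scale stand-ins for chromosomes (tens of kb rather
    than tens of Mb) so that whole property suites run in seconds; the
    structural features — macro/micro GC contrast, fragmentation,
    inversions, 100-N chimera joints, decoys, substitutions — are the
    ones the pipeline must be robust to.
    """

    seed: int = 0
    n_macro: int = 2
    n_micro: int = 4
    macro_len_range: tuple[int, int] = (40_000, 80_000)
    micro_len_range: tuple[int, int] = (8_000, 20_000)
    gc_macro: float = 0.40
    gc_micro: float = 0.52
    fragments_per_chromosome: tuple[int, int] = (2, 5)
    inversion_prob: float = 0.3
    chimera_count: int = 2
    chimera_joint: int = 100  # bp of Ns joining the two parts
    unplaced_fraction: float = 0.0
    substitution_rate: float = 0.001
    # knobs for corrupt_reference_assembly
    missing_count: int = 2
    contigs_per_missing: tuple[int, int] = (2, 4)
    unplaced_contig_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "inversion_prob",
            "unplaced_fraction",
            "substitution_rate",
            "unplaced_contig_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureConfigError(f"{name} must be in [0,1], got {v}")
        for name in (
            "macro_len_range",
            "micro_len_range",
            "fragments_per_chromosome",
            "contigs_per_missing",
        ):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise FixtureConfigError(f"empty range for {name}: ({lo},{hi})")
        if self.n_macro < 0 or self.n_micro < 0 or self.n_macro + self.n_micro < 1:
            raise FixtureConfigError("need at least one chromosome")
        if self.chimera_joint < 1:
            raise FixtureConfigError("chimera_joint must be >= 1")


PRESETS: dict[str, FixtureConfig] = {
    # clean study conditions: no decoys, so every scaffold has a true home
    "small": FixtureConfig(),
    # larger genome with decoys, closer to a real project's inputs
    "chicken-like": FixtureConfig(
        n_macro=5,
        n_micro=10,
        macro_len_range=(80_000, 150_000),
        micro_len_range=(10_000, 30_000),
        gc_micro=0.54,
        fragments_per_chromosome=(3, 6),
        unplaced_fraction=0.08,
        substitution_rate=0.002,
    ),
    # minimal genome for bulk property suites
    "tiny": FixtureConfig(
        n_macro=1,
        n_micro=2,
        macro_len_range=(3_000, 6_000),
        micro_len_range=(1_000, 2_000),
        fragments_per_chromosome=(1, 3),
        chimera_count=1,
    ),
}


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldPart:
    """One template-derived piece of a scaffold."""

    source_id: str
    src_span: tuple[int, int]  # 0-based half-open on the source chromosome
    orientation: str  # '+' or '-'
    q_span: tuple[int, int]  # 0-based half-open on the scaffold


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    parts: list[ScaffoldPart]
    joints: list[tuple[int, int]] = field(default_factory=list)
    substitutions: list[int] = field(default_factory=list)
    decoy: bool = False

    @property
    def chimeric(self) -> bool:
        return len({p.source_id for p in self.parts}) > 1


@dataclass
class TruthManifest:
    """Everything needed to reconstruct and verify the derived assembly."""

    template_lengths: dict[str, int]
    scaffolds: dict[str, ScaffoldTruth] = field(default_factory=dict)
    missing_chromosomes: list[str] = field(default_factory=list)

    def reconstruct(self, template: Mapping[str, str], scaffold_id: str) -> str:
        """Rebuild a (non-decoy) scaffold from the template, pre-substitution."""
        truth = self.scaffolds[scaffold_id]
        if truth.decoy:
            raise ValueError(f"{scaffold_id} is a decoy; not template-derived")
        out: list[str] = []
        pos = 0
        for part in truth.parts:
            if part.q_span[0] > pos:  # joint Ns before this part
                out.append("N" * (part.q_span[0] - pos))
            sub = template[part.source_id][part.src_span[0] : part.src_span[1]]
            out.append(reverse_complement(sub) if part.orientation == "-" else sub)
            pos = part.q_span[1]
        return "".join(out)

    def true_order(self, chromosome_id: str) -> list[str]:
        """Non-chimeric scaffold ids on one chromosome, in template order."""
        entries = [
            (t.parts[0].src_span[0], sid)
            for sid, t in self.scaffolds.items()
            if not t.decoy and not t.chimeric and t.parts[0].source_id == chromosome_id
        ]
        return [sid for _, sid in sorted(entries)]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def generate_template(
    config: FixtureConfig,
) -> tuple[list[SequenceRecord], dict[str, float]]:
    """i.i.d.-base template chromosomes at the class GC targets.

    Macro-chromosomes come first (``chr1``..), then micro-chromosomes;
    deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    gc_targets: dict[str, float] = {}
    idx = 1
    for count, len_range, gc in (
        (config.n_macro, config.macro_len_range, config.gc_macro),
        (config.n_micro, config.micro_len_range, config.gc_micro),
    ):
        for _ in range(count):
            name = f"chr{idx}"
            length = int(rng.integers(len_range[0], len_range[1] + 1))
            records.append(SequenceRecord(name, _random_seq(rng, length, gc)))
            gc_targets[name] = gc
            idx += 1
    return records, gc_targets


def _fragment_chromosome(
    rng: np.random.Generator, length: int, n_frags: int
) -> list[tuple[int, int]]:
    """Tile [0, length) with n_frags non-empty fragments."""
    n_frags = min(n_frags, length)
    if n_frags <= 1:
        return [(0, length)]
    cuts = sorted(rng.choice(np.arange(1, length), size=n_frags - 1, replace=False))
    bounds = [0, *map(int, cuts), length]
    return list(zip(bounds[:-1], bounds[1:]))


def _plant_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, list[int]]:
    if rate <= 0:
        return seq, []
    chars = np.array(list(seq))
    eligible = np.flatnonzero(np.isin(chars, _BASES))
    n_subs = int(rng.binomial(len(eligible), rate))
    if n_subs == 0:
        return seq, []
    positions = rng.choice(eligible, size=n_subs, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars), sorted(int(p) for p in positions)


def derive_assembly(
    template: Sequence[SequenceRecord], config: FixtureConfig
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthManifest]:
    """Fragment/invert/chimerize/corrupt the template into a draft assembly.

    Returns ``(scaffolds, decoy unplaced records, manifest)``.  A
    fragment becomes, in decreasing priority: one half of a chimeric
    scaffold (``chimera_count`` pairs from different chromosomes joined
    by ``chimera_joint`` Ns), a shuffled decoy (``unplaced_fraction``),
    or a scaffold of its own.
    """
    rng = np.random.default_rng(config.seed + 1)
    tmap = {rec.id: rec.seq for rec in template}
    manifest = TruthManifest({rec.id: len(rec.seq) for rec in template})

    fragments: list[tuple[str, int, int]] = []
    for rec in template:
        lo, hi = config.fragments_per_chromosome
        n_frags = int(rng.integers(lo, hi + 1))
        for start, end in _fragment_chromosome(rng, len(rec.seq), n_frags):
            fragments.append((rec.id, start, end))

    # pair fragments from different chromosomes into chimeras
    pool = list(range(len(fragments)))
    chimera_pairs: list[tuple[int, int]] = []
    for _ in range(config.chimera_count):
        candidates = [
            (i, j)
            for ai, i in enumerate(pool)
            for j in pool[ai + 1 :]
            if fragments[i][0] != fragments[j][0]
        ]
        if not candidates:
            raise FixtureConfigError(
                f"cannot form {config.chimera_count} chimeras from available fragments"
            )
        i, j = candidates[int(rng.integers(len(candidates)))]
        chimera_pairs.append((i, j))
        pool.remove(i)
        pool.remove(j)

    n_decoys = int(round(config.unplaced_fraction * len(pool)))
    decoy_ids = set(
        int(x) for x in rng.choice(pool, size=n_decoys, replace=False)
    ) if n_decoys else set()

    def orient() -> str:
        return "-" if rng.random() < config.inversion_prob else "+"

    scaffolds: list[SequenceRecord] = []
    decoys: list[SequenceRecord] = []
    counter = 0

    def finish(parts: list[ScaffoldPart], joints: list[tuple[int, int]], seq: str):
        nonlocal counter
        counter += 1
        sid = f"scaffold_{counter}"
        seq, subs = _plant_substitutions(rng, seq, config.substitution_rate)
        scaffolds.append(SequenceRecord(sid, seq))
        manifest.scaffolds[sid] = ScaffoldTruth(sid, parts, joints, subs)

    for i, j in chimera_pairs:
        (ca, sa, ea), (cb, sb, eb) = fragments[i], fragments[j]
        oa, ob = orient(), orient()
        seq_a = tmap[ca][sa:ea]
        seq_b = tmap[cb][sb:eb]
        if oa == "-":
            seq_a = reverse_complement(seq_a)
        if ob == "-":
            seq_b = reverse_complement(seq_b)
        joint = (len(seq_a), len(seq_a) + config.chimera_joint)
        parts = [
            ScaffoldPart(ca, (sa, ea), oa, (0, len(seq_a))),
            ScaffoldPart(cb, (sb, eb), ob, (joint[1], joint[1] + len(seq_b))),
        ]
        finish(parts, [joint], seq_a + "N" * config.chimera_joint + seq_b)

    for idx in pool:
        chrom, start, end = fragments[idx]
        frag = tmap[chrom][start:end]
        if idx in decoy_ids:
            counter_d = len(decoys) + 1
            shuffled = "".join(rng.permutation(list(frag)))
            did = f"decoy_{counter_d}"
            decoys.append(SequenceRecord(did, shuffled))
            manifest.scaffolds[did] = ScaffoldTruth(
                did, [ScaffoldPart(chrom, (start, end), "+", (0, end - start))],
                decoy=True,
            )
            continue
        o = orient()
        seq = reverse_complement(frag) if o == "-" else frag
        finish([ScaffoldPart(chrom, (start, end), o, (0, end - start))], [], seq)

    return scaffolds, decoys, manifest


def emit_truth_alignments(manifest: TruthManifest) -> list[AlignmentHit]:
    """One exact-coordinate hit per template-derived scaffold part.

    Identity reflects the substitutions planted inside the part's query
    span; decoys emit nothing (no template homology survives a
    per-base shuffle).
    """
    hits: list[AlignmentHit] = []
    for truth in manifest.scaffolds.values():
        if truth.decoy:
            continue
        for part in truth.parts:
            qs, qe = part.q_span
            n_subs = sum(1 for p in truth.substitutions if qs <= p < qe)
            identity = round(1.0 - n_subs / (qe - qs), 6)
            hits.append(
                AlignmentHit(
                    truth.scaffold_id,
                    part.source_id,
                    qs,
                    qe,
                    part.src_span[0],
                    part.src_span[1],
                    part.orientation,
                    identity,
                )
            )
    return hits


def corrupt_reference_assembly(
    template: Sequence[SequenceRecord], config: FixtureConfig
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthManifest]:
    """Plant the mis-scaffolding pattern a correction pass must undo.

    The last ``missing_count`` (micro-)chromosomes are deleted from the
    assembly; each is cut into contigs which are either appended (with
    100-N joints, possibly inverted) onto a surviving host chromosome or
    dropped into the unplaced pool.  The manifest records the diaspora
    so a corrector's rebuilds can be checked by provenance set equality.
    """
    if len(template) < 4:
        raise FixtureConfigError("corrupt_reference_assembly needs >= 4 chromosomes")
    if not 1 <= config.missing_count <= len(template) - 2:
        raise FixtureConfigError("missing_count out of range")
    rng = np.random.default_rng(config.seed + 2)
    missing = [rec.id for rec in template[-config.missing_count :]]
    survivors = [rec for rec in template if rec.id not in missing]

    manifest = TruthManifest(
        {rec.id: len(rec.seq) for rec in template},
        missing_chromosomes=missing,
    )
    # hosts start as intact copies of their template chromosome
    host_parts: dict[str, list[ScaffoldPart]] = {}
    host_seqs: dict[str, str] = {}
    host_joints: dict[str, list[tuple[int, int]]] = {}
    for rec in survivors:
        host_parts[rec.id] = [
            ScaffoldPart(rec.id, (0, len(rec.seq)), "+", (0, len(rec.seq)))
        ]
        host_seqs[rec.id] = rec.seq
        host_joints[rec.id] = []

    unplaced: list[SequenceRecord] = []
    n_unplaced = 0
    tmap = {rec.id: rec.seq for rec in template}
    for chrom in missing:
        lo, hi = config.contigs_per_missing
        n_contigs = int(rng.integers(lo, hi + 1))
        for start, end in _fragment_chromosome(rng, len(tmap[chrom]), n_contigs):
            frag = tmap[chrom][start:end]
            if rng.random() < config.unplaced_contig_fraction:
                n_unplaced += 1
                uid = f"contig_{n_unplaced}"
                unplaced.append(SequenceRecord(uid, frag))
                manifest.scaffolds[uid] = ScaffoldTruth(
                    uid, [ScaffoldPart(chrom, (start, end), "+", (0, end - start))]
                )
            else:
                host = survivors[int(rng.integers(len(survivors)))].id
                o = "-" if rng.random() < config.inversion_prob else "+"
                piece = reverse_complement(frag) if o == "-" else frag
                offset = len(host_seqs[host])
                joint = (offset, offset + 100)
                host_joints[host].append(joint)
                host_seqs[host] = host_seqs[host] + "N" * 100 + piece
                host_parts[host].append(
                    ScaffoldPart(chrom, (start, end), o, (joint[1], joint[1] + len(piece)))
                )

    assembly = [SequenceRecord(h, host_seqs[h]) for h in host_seqs]
    for rec in assembly:
        manifest.scaffolds[rec.id] = ScaffoldTruth(
            rec.id, host_parts[rec.id], host_joints[rec.id]
        )
    return assembly, unplaced, manifest


# ---------------------------------------------------------------------------
# Truth-free exact-anchor alignment (for scoring decoys etc.)
# ---------------------------------------------------------------------------


def anchor_align(
    query: SequenceRecord,
    template: Sequence[SequenceRecord],
    k: int = 31,
    max_occurrences: int = 4,
) -> list[AlignmentHit]:
    """Chain exact k-mer matches into gapless alignment hits.

    A deliberately simple seed-and-chain scorer: index every template
    k-mer, look up each query k-mer (both strands), and merge matches
    sharing a (target, strand, diagonal) into one hit.  Good enough to
    demonstrate that base-shuffled decoys retain no long homology; not a
    general-purpose aligner.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for rec in template:
        seq = rec.seq.upper()
        for p in range(len(seq) - k + 1):
            km = seq[p : p + k]
            if "N" in km:
                continue
            bucket = index.setdefault(km, [])
            if len(bucket) <= max_occurrences:
                bucket.append((rec.id, p))
    qseq = query.seq.upper()
    # chains keyed by (target, strand, diagonal); diagonal is t-i for '+',
    # t+i for '-' (constant along a gapless reverse-complement match)
    chains: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    for i in range(len(qseq) - k + 1):
        km = qseq[i : i + k]
        if "N" in km:
            continue
        for tid, p in index.get(km, []):
            chains.setdefault((tid, "+", p - i), []).append((i, p))
        for tid, p in index.get(reverse_complement(km), []):
            chains.setdefault((tid, "-", p + i), []).append((i, p))
    hits: list[AlignmentHit] = []
    for (tid, strand, _), anchors in sorted(chains.items()):
        qs = min(i for i, _ in anchors)
        qe = max(i for i, _ in anchors) + k
        ts = min(p for _, p in anchors)
        te = max(p for _, p in anchors) + k
        hits.append(AlignmentHit(query.id, tid, qs, qe, ts, te, strand))
    return hits
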