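from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refchrom.chrom_builder import (
    UNPLACED,
    assign_scaffold,
    build_chromosomes,
    detect_and_split_chimeras,
    mapped_ratio,
    merge_intervals,
    orient_and_key,
    place_assembly,
    reverse_complement,
    split_at_n_runs,
    PlacementDecision,
)
from refchrom.io_formats import AlignmentHit, RefchromError, SequenceRecord

intervals = st.lists(
    st.tuples(st.integers(0, 500), st.integers(1, 100)).map(lambda t: (t[0], t[0] + t[1])),
    max_size=20,
)


def hit(q=(0, 100), t=(0, 100), strand="+", query="q", target="chrA", identity=1.0):
    return AlignmentHit(query, target, q[0], q[1], t[0], t[1], strand, identity)


class TestMergeIntervals:
    def test_overlap_and_disjoint(self):
        assert merge_intervals([(0, 100), (50, 150), (200, 250)]) == [(0, 150), (200, 250)]

    def test_empty(self):
        assert merge_intervals([]) == []

    def test_touching_intervals_merge(self):
        assert merge_intervals([(0, 10), (10, 20)]) == [(0, 20)]

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            merge_intervals([(5, 5)])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(ivs=intervals)
    def test_union_preserved_and_disjoint(self, ivs):
        merged = merge_intervals(ivs)
        covered = set()
        for s, e in ivs:
            covered.update(range(s, e))
        out = set()
        for s, e in merged:
            assert s < e
            out.update(range(s, e))
        assert out == covered
        for (s0, e0), (s1, e1) in zip(merged, merged[1:]):
            assert e0 < s1  # sorted, disjoint, non-touching


class TestMappedRatio:
    def test_partial_coverage(self):
        hits = [hit(q=(0, 120)), hit(q=(100, 180))]  # merged 180 of 300
        assert mapped_ratio(hits, 300, 1_000_000) == pytest.approx(0.6)

    def test_full_query_longer_target(self):
        assert mapped_ratio([hit(q=(0, 300))], 300, 1_000_000) == 1.0

    def test_empty_hits(self):
        assert mapped_ratio([], 100, 100) == 0.0

    def test_bruteforce_coverage_oracle(self):
        """Merged-interval ratio equals per-base coverage counting."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            qlen = int(rng.integers(10, 400))
            tlen = int(rng.integers(10, 400))
            n = int(rng.integers(0, 8))
            hits = []
            covered = np.zeros(qlen, dtype=bool)
            for _ in range(n):
                s = int(rng.integers(0, qlen))
                e = int(rng.integers(s + 1, qlen + 1))
                hits.append(hit(q=(s, e)))
                covered[s:e] = True
            expected = min(1.0, covered.sum() / min(qlen, tlen))
            assert mapped_ratio(hits, qlen, tlen) == pytest.approx(expected)


class TestAssignScaffold:
    lengths = {"chrA": 10_000, "chrB": 10_000}

    def test_clear_winner(self):
        per = {"chrA": [hit(q=(0, 80))], "chrB": [hit(q=(0, 30), target="chrB")]}
        d = assign_scaffold(per, 100, self.lengths, query_id="q")
        assert d.chromosome_id == "chrA" and d.ratio == pytest.approx(0.8)

    def test_below_threshold_unplaced(self):
        per = {"chrA": [hit(q=(0, 40))], "chrB": [hit(q=(0, 45), target="chrB")]}
        d = assign_scaffold(per, 100, self.lengths)
        assert d.chromosome_id == UNPLACED and d.ratio == pytest.approx(0.45)

    def test_ratio_exactly_half_not_assigned(self):
        # the assignment rule is strictly greater-than
        d = assign_scaffold({"chrA": [hit(q=(0, 50))]}, 100, self.lengths)
        assert d.chromosome_id == UNPLACED

    def test_tie_breaks_by_aligned_bases_then_name(self):
        per = {
            "chrB": [hit(q=(0, 60), target="chrB"), hit(q=(0, 60), target="chrB")],
            "chrA": [hit(q=(0, 60))],
        }
        # equal ratios (0.6); chrB has 120 aligned bases vs chrA's 60
        d = assign_scaffold(per, 100, self.lengths)
        assert d.chromosome_id == "chrB"
        per2 = {"chrB": [hit(q=(0, 60), target="chrB")], "chrA": [hit(q=(0, 60))]}
        assert assign_scaffold(per2, 100, self.lengths).chromosome_id == "chrA"

    def test_empty_map_unplaced(self):
        d = assign_scaffold({}, 100, self.lengths)
        assert d.chromosome_id == UNPLACED and d.ratio == 0.0


class TestOrientAndKey:
    def test_majority_strand(self):
        o, _ = orient_and_key([hit(q=(0, 500)), hit(q=(0, 100), strand="-")])
        assert o == "+"
        o, _ = orient_and_key([hit(q=(0, 100)), hit(q=(0, 500), strand="-")])
        assert o == "-"

    def test_tie_is_plus(self):
        o, _ = orient_and_key([hit(q=(0, 100)), hit(q=(0, 100), strand="-")])
        assert o == "+"

    def test_weighted_midpoint(self):
        hits = [hit(q=(0, 100), t=(950, 1050)), hit(q=(100, 200), t=(2950, 3050))]
        _, key = orient_and_key(hits)
        assert key == pytest.approx(2000.0)

    def test_empty_is_error(self):
        with pytest.raises(RefchromError):
            orient_and_key([])


class TestSplitAtNRuns:
    def test_long_run_splits(self):
        rec = SequenceRecord("s", "ACGT" + "N" * 100 + "GGCC")
        assert split_at_n_runs(rec, 10) == [((0, 4), "ACGT"), ((104, 108), "GGCC")]

    def test_short_run_stays(self):
        rec = SequenceRecord("s", "ACNNNGT")
        assert split_at_n_runs(rec, 10) == [((0, 7), "ACNNNGT")]

    def test_all_n_is_empty(self):
        assert split_at_n_runs(SequenceRecord("s", "NNNN"), 2) == []

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGTN", min_size=1, max_size=300), min_gap=st.integers(1, 20))
    def test_reconstruction(self, seq, min_gap):
        """Segments plus the intervening N runs tile the parent exactly."""
        rec = SequenceRecord("s", seq)
        segs = split_at_n_runs(rec, min_gap)
        rebuilt = list("N" * len(seq))
        for (s, e), sub in segs:
            assert seq[s:e] == sub
            rebuilt[s:e] = sub
        assert "".join(rebuilt) == seq.replace("n", "N") or "".join(rebuilt) == seq


class TestChimeras:
    lengths = {"chrA": 50_000, "chrB": 50_000}

    def _chimera_record(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 1000))
        b = "".join(rng.choice(list("ACGT"), 1200))
        return SequenceRecord("s", a + "N" * 100 + b)

    def test_split_at_joint(self):
        rec = self._chimera_record()
        hits = [
            hit(q=(0, 1000), t=(5000, 6000), query="s"),
            hit(q=(1100, 2300), t=(9000, 10200), query="s", target="chrB"),
        ]
        decisions = detect_and_split_chimeras(rec, hits, self.lengths, 10)
        assert [(d.segment_span, d.chromosome_id) for d in decisions] == [
            ((0, 1000), "chrA"), ((1100, 2300), "chrB")]
        assert all("split_chimera" in d.flags for d in decisions)

    def test_consistent_segments_keep_whole(self):
        rec = self._chimera_record()
        hits = [
            hit(q=(0, 1000), t=(5000, 6000), query="s"),
            hit(q=(1100, 2300), t=(9000, 10200), query="s"),
        ]
        (d,) = detect_and_split_chimeras(rec, hits, self.lengths, 10)
        assert d.segment_span == (0, 2300) and d.chromosome_id == "chrA"

    def test_conflict_without_joint_flagged_not_split(self):
        rng = np.random.default_rng(2)
        rec = SequenceRecord("s", "".join(rng.choice(list("ACGT"), 2000)))
        hits = [
            hit(q=(0, 1300), t=(0, 1300), query="s"),
            hit(q=(900, 2000), t=(0, 1100), query="s", target="chrB"),
        ]
        (d,) = detect_and_split_chimeras(rec, hits, self.lengths, 10)
        assert d.chromosome_id == "chrA"
        assert "possible_chimera_no_joint" in d.flags


class TestBuildChromosomes:
    def test_render_with_gap_and_revcomp(self):
        a = SequenceRecord("a", "A" * 100)
        b = SequenceRecord("b", "ACGT" * 50)
        decisions = [
            PlacementDecision("a", (0, 100), "chr1", 1.0, "+", 10.0),
            PlacementDecision("b", (0, 200), "chr1", 1.0, "-", 20.0),
        ]
        builds, unplaced = build_chromosomes(decisions, [a, b], gap=500)
        assert not unplaced
        (build,) = builds
        assert build.rendered_length == 800
        rendered = build.render({"a": a.seq, "b": b.seq})
        assert len(rendered) == 800
        assert rendered[:100] == "A" * 100
        assert rendered[100:600] == "N" * 500
        assert rendered[600:] == reverse_complement(b.seq)

    def test_single_scaffold_is_identity(self):
        a = SequenceRecord("a", "ACGTNACGT")
        builds, _ = build_chromosomes(
            [PlacementDecision("a", (0, 9), "chr1", 1.0, "+", 0.0)], [a]
        )
        assert builds[0].render({"a": a.seq}) == a.seq

    def test_gap_zero_concatenates(self):
        a = SequenceRecord("a", "AAAA")
        b = SequenceRecord("b", "CCCC")
        decisions = [
            PlacementDecision("a", (0, 4), "chr1", 1.0, "+", 1.0),
            PlacementDecision("b", (0, 4), "chr1", 1.0, "+", 2.0),
        ]
        builds, _ = build_chromosomes(decisions, [a, b], gap=0)
        assert builds[0].render({"a": a.seq, "b": b.seq}) == "AAAACCCC"

    def test_overlapping_claims_rejected(self):
        a = SequenceRecord("a", "ACGTACGT")
        decisions = [
            PlacementDecision("a", (0, 5), "chr1", 1.0, "+", 0.0),
            PlacementDecision("a", (4, 8), "chr2", 1.0, "+", 0.0),
        ]
        with pytest.raises(RefchromError, match="overlapping"):
            build_chromosomes(decisions, [a])


def test_reverse_complement_involution():
    rng = np.random.default_rng(3)
    for _ in range(20):
        s = "".join(rng.choice(list("ACGTNacgtn"), 50))
        assert reverse_complement(reverse_complement(s)) == s
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAcc") == "ggTT"


class TestPlacementRecovery:
    def test_true_chromosome_orientation_and_order(self, small_bundle):
        """Clean fixture: every scaffold recovers its true home and strand."""
        b = small_bundle
        decisions, builds, unplaced = place_assembly(
            b.scaffolds, b.hits, b.template_lengths
        )
        assert not unplaced
        for d in decisions:
            truth = b.manifest.scaffolds[d.query_id]
            if truth.chimeric:
                continue
            part = truth.parts[0]
            assert d.chromosome_id == part.source_id
            assert d.orientation == part.orientation
        # within-chromosome order of whole scaffolds matches template order
        chimeric = {s for s, t in b.manifest.scaffolds.items() if t.chimeric}
        for build in builds:
            got = [s.query_id for s in build.segments if s.query_id not in chimeric]
            assert got == b.manifest.true_order(build.chromosome_id)

    def test_base_conservation(self, small_bundle):
        """Non-N content is conserved through build (strand-insensitively)."""
        b = small_bundle
        decisions, builds, unplaced = place_assembly(
            b.scaffolds, b.hits, b.template_lengths
        )
        seqs = {r.id: r.seq for r in b.scaffolds}

        def strand_free(counter):
            return {
                "AT": counter["A"] + counter["T"],
                "CG": counter["C"] + counter["G"],
            }

        out = Counter()
        for build in builds:
            out += Counter(build.render(seqs).upper())
        for rec in unplaced:
            out += Counter(rec.seq.upper())
        before = Counter()
        for rec in b.scaffolds:
            before += Counter(rec.seq.upper())
        # joint Ns are dropped on splitting; non-N bases must survive exactly
        assert strand_free(out) == strand_free(before)
        # stronger: each placed segment is recoverable from its scaffold
        for build in builds:
            rendered = build.render(seqs)
            pos = 0
            for i, seg in enumerate(build.segments):
                if i:
                    pos += build.inter_segment_gap
                sub = seqs[seg.query_id][seg.span[0] : seg.span[1]]
                if seg.orientation == "-":
                    sub = reverse_complement(sub)
                assert rendered[pos : pos + len(sub)] == sub
                pos += len(sub)
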