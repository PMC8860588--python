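import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import oracle_scan
from g4kit.intervals import GenomicInterval, Peak
from g4kit.io import SequenceRecord
from g4kit.scan import (
    INTERSTRAND_COMPOSITIONS,
    NONCANONICAL_COMPOSITIONS,
    PQSPatternSpec,
    _dual_composition,
    _scan_interstrand_any,
    cpg_track,
    fraction_peaks_with_pqs,
    pqs_coverage,
    pqs_union,
    reverse_complement,
    scan_interstrand,
    scan_intrastrand,
)


def spans(matches):
    return [(m.start, m.end) for m in matches]


class TestPatternSpec:
    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            PQSPatternSpec.for_class("bulged")

    def test_interstrand_composition_validated(self):
        with pytest.raises(ValueError):
            PQSPatternSpec.for_class("interstrand", "BBBB")
        spec = PQSPatternSpec.for_class("interstrand", "AABB")
        assert (spec.loop_min, spec.loop_max, spec.min_run) == (1, 7, 3)

    def test_class_parameters(self):
        canonical = PQSPatternSpec.for_class("canonical")
        extended = PQSPatternSpec.for_class("extended")
        two = PQSPatternSpec.for_class("two_tetrad")
        assert (canonical.min_run, canonical.loop_max) == (3, 7)
        assert (extended.min_run, extended.loop_max) == (3, 12)
        assert (two.min_run, two.loop_max, two.variable_blocks) == (2, 12, True)


class TestIntrastrand:
    def test_minimal_canonical_plus(self):
        rec = SequenceRecord("chr1", "GGGAGGGAGGGAGGG")
        (m,) = scan_intrastrand(rec, "canonical")
        assert (m.start, m.end, m.strand, m.composition) == (0, 15, "+", "AAAA")
        assert m.matched_seq == rec.sequence

    def test_minimal_canonical_minus(self):
        rec = SequenceRecord("chr1", "CCCTCCCTCCCTCCC")
        (m,) = scan_intrastrand(rec, "canonical")
        assert (m.start, m.end, m.strand) == (0, 15, "-")
        assert m.matched_seq == rec.sequence  # reference-strand slice

    def test_minimal_two_tetrad(self):
        rec = SequenceRecord("chr1", "GGAGGAGGAGG")
        (m,) = scan_intrastrand(rec, "two_tetrad")
        assert (m.start, m.end, m.strand) == (0, 11, "+")

    def test_n_breaks_runs_and_loops(self):
        rec = SequenceRecord("chr1", "GGGNGGGAGGGAGGG")
        assert scan_intrastrand(rec, "canonical", strands=("+",)) == []

    def test_invalid_class(self):
        with pytest.raises(ValueError):
            scan_intrastrand(SequenceRecord("c", "ACGT"), "interstrand")

    def test_overlapping_mode_enumerates_all_placements(self):
        # two possible final runs: G3 L1 G3 L1 G3 L1 G3 ... G3
        rec = SequenceRecord("chr1", "GGGAGGGAGGGAGGGAGGG")
        non_overlap = spans(scan_intrastrand(rec, "canonical", strands=("+",)))
        overlap = spans(
            scan_intrastrand(rec, "canonical", overlapping=True, strands=("+",))
        )
        assert set(non_overlap) <= set(overlap)
        assert (0, 15) in overlap and (4, 19) in overlap and (0, 19) in overlap


class TestInterstrand:
    def test_aabb_instance(self):
        (m,) = scan_interstrand(SequenceRecord("c", "GGGAGGGACCCACCC"), "AABB")
        assert (m.start, m.end, m.strand) == (0, 15, ".")

    def test_abab_instance(self):
        (m,) = scan_interstrand(SequenceRecord("c", "GGGACCCAGGGACCC"), "ABAB")
        assert (m.start, m.end) == (0, 15)

    def test_aaaa_equals_canonical_plus_strand(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        rec = SequenceRecord("c", seq)
        inter = spans(scan_interstrand(rec, "AAAA"))
        intra = spans(scan_intrastrand(rec, "canonical", strands=("+",)))
        assert inter == intra
        assert all(m.strand == "+" for m in scan_interstrand(rec, "AAAA"))

    def test_composition_validated(self):
        with pytest.raises(ValueError):
            scan_interstrand(SequenceRecord("c", "ACGT"), "BBAA")


class TestOracleEquivalence:
    """Scanner (regex engine) vs independent recursive-descent enumeration."""

    @pytest.mark.parametrize("class_id", ["canonical", "extended", "two_tetrad"])
    def test_intrastrand_non_overlapping(self, class_id, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            rec = SequenceRecord("c", seq)
            got = spans(scan_intrastrand(rec, class_id, strands=("+",)))
            assert got == oracle_scan(seq, class_id)
            rc = reverse_complement(seq)
            got_minus = spans(scan_intrastrand(rec, class_id, strands=("-",)))
            expected = sorted(
                (len(seq) - e, len(seq) - s) for s, e in oracle_scan(rc, class_id)
            )
            assert got_minus == expected

    @pytest.mark.parametrize("composition", INTERSTRAND_COMPOSITIONS)
    def test_interstrand_non_overlapping(self, composition, rng):
        for _ in range(3):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            rec = SequenceRecord("c", seq)
            got = spans(scan_interstrand(rec, composition))
            dual = _dual_composition(composition)
            if composition <= dual:
                expected = oracle_scan(seq, "interstrand", composition)
            else:
                rc = reverse_complement(seq)
                expected = sorted(
                    (len(seq) - e, len(seq) - s)
                    for s, e in oracle_scan(rc, "interstrand", dual)
                )
            assert got == expected


DNA = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestStrandSymmetry:
    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(seq=DNA)
    def test_intrastrand_mirror(self, seq):
        if not seq:
            return
        rec = SequenceRecord("c", seq)
        rc_rec = SequenceRecord("c", reverse_complement(seq))
        n = len(seq)
        flip = {"+": "-", "-": "+"}
        for class_id in ("canonical", "extended", "two_tetrad"):
            fwd = scan_intrastrand(rec, class_id)
            rev = scan_intrastrand(rc_rec, class_id)
            assert sorted((m.start, m.end, m.strand) for m in rev) == sorted(
                (n - m.end, n - m.start, flip[m.strand]) for m in fwd
            )

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(seq=DNA)
    def test_interstrand_dual_mirror(self, seq):
        if not seq:
            return
        rec = SequenceRecord("c", seq)
        rc_rec = SequenceRecord("c", reverse_complement(seq))
        n = len(seq)
        for composition in ("AAAB", "ABBB", "AAAA"):
            fwd = _scan_interstrand_any(rec, composition)
            rev = _scan_interstrand_any(rc_rec, _dual_composition(composition))
            assert sorted(rev) == sorted((n - e, n - s) for s, e in fwd)


class TestDerivedTracks:
    def test_union_merges_across_classes(self):
        by_class = {
            "canonical": [GenomicInterval("c", 0, 15)],
            "extended": [GenomicInterval("c", 0, 20)],
        }
        assert [(m.start, m.end) for m in pqs_union(by_class)] == [(0, 20)]

    def test_union_disjoint_sorted(self):
        by_class = {
            "a": [GenomicInterval("c", 50, 60)],
            "b": [GenomicInterval("c", 0, 10)],
        }
        assert [(m.start, m.end) for m in pqs_union(by_class)] == [
            (0, 10),
            (50, 60),
        ]

    def test_union_empty_selection(self):
        assert pqs_union({"canonical": [GenomicInterval("c", 0, 5)]}, []) == []

    def test_noncanonical_set_excludes_aaaa(self):
        assert "AAAA" not in NONCANONICAL_COMPOSITIONS
        assert len(NONCANONICAL_COMPOSITIONS) == 7

    def test_coverage_occupancy(self):
        track = pqs_coverage([GenomicInterval("c", 0, 10)], {"c": 20}, 5)
        assert list(track.data["c"]) == [1.0, 1.0, 0.0, 0.0]

    def test_coverage_counts_bases_once(self):
        track = pqs_coverage(
            [GenomicInterval("c", 0, 8), GenomicInterval("c", 4, 10)],
            {"c": 10},
            5,
        )
        assert list(track.data["c"]) == [1.0, 1.0]

    def test_coverage_empty(self):
        track = pqs_coverage([], {"c": 10}, 5)
        assert list(track.data["c"]) == [0.0, 0.0]

    def test_cpg_examples(self):
        assert [
            (m.start, m.end) for m in cpg_track(SequenceRecord("c", "ACGCGT"))
        ] == [(1, 3), (3, 5)]
        assert cpg_track(SequenceRecord("c", "GGGG")) == []
        assert [
            (m.start, m.end) for m in cpg_track(SequenceRecord("c", "CGCG"))
        ] == [(0, 2), (2, 4)]

    def test_fraction_peaks_with_pqs(self):
        peaks = [Peak("c", i * 100, i * 100 + 10) for i in range(4)]
        pqs = [GenomicInterval("c", 0, 5), GenomicInterval("c", 100, 215)]
        assert fraction_peaks_with_pqs(peaks, pqs) == 0.75
        assert fraction_peaks_with_pqs(peaks, []) == 0.0
        assert fraction_peaks_with_pqs(peaks, [GenomicInterval("c", 0, 400)]) == 1.0
        with pytest.raises(ValueError):
            fraction_peaks_with_pqs([], pqs)
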