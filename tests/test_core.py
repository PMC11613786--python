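"""Data-model invariants: intervals, segments, walks, breakpoint counts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgrkit.core import (
    DerivativeWalk,
    Dosage,
    GenomicInterval,
    Junction,
    Segment,
    WalkStep,
    check_no_same_dosage_overlap,
    count_case_breakpoints,
    derivative_adjacent,
    mb,
    reference_adjacent,
    segment_length,
    total_length,
)


class TestGenomicInterval:
    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr21", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr21", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr21", -1, 5)

    @given(
        start=st.integers(min_value=1, max_value=10**8),
        length=st.integers(min_value=1, max_value=10**7),
    )
    @settings(max_examples=100, derandomize=True)
    def test_one_based_round_trip(self, start, length):
        """1-based inclusive -> half-open -> 1-based is the identity."""
        end = start + length - 1
        iv = GenomicInterval.from_1based("chr21", start, end)
        assert iv.to_1based() == (start, end)
        assert iv.length() == end - start + 1


class TestSegmentLengths:
    @pytest.mark.parametrize(
        "label, expected",
        [("D", 1_032_304), ("L", 3_882_480)],
    )
    def test_tabulated_segment_lengths(self, rd_p505, label, expected):
        seg = {s.label: s for s in rd_p505.segments}[label]
        assert segment_length(seg) == expected

    def test_duplicated_material_totals(self, rd_p505, rd_p01):
        dup_nt = total_length(rd_p505.segments, {Dosage.DUP})
        assert dup_nt == 10_339_425
        assert mb(dup_nt) == 10.3
        del_nt = total_length(rd_p01.segments, {Dosage.DEL})
        assert del_nt == 13_443_065
        assert mb(del_nt) == 13.4

    def test_empty_selection_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert total_length([], None) == 0


class TestReferenceAdjacency:
    def test_abutting_table_rows(self, rd_p26):
        segs = {s.label: s for s in rd_p26.segments}
        assert reference_adjacent(segs["B"].interval, segs["C"].interval)
        assert reference_adjacent(segs["C"].interval, segs["D"].interval)

    @pytest.mark.parametrize(
        "a, b, expected",
        [((0, 10), (10, 20), True), ((0, 10), (11, 20), False)],
    )
    def test_half_open_abutment(self, a, b, expected):
        assert (
            reference_adjacent(
                GenomicInterval("c", *a), GenomicInterval("c", *b)
            )
            is expected
        )

    def test_different_contigs_not_adjacent(self):
        assert not reference_adjacent(
            GenomicInterval("c1", 0, 10), GenomicInterval("c2", 10, 20)
        )


class TestCaseTables:
    @pytest.mark.parametrize("case", ["rd_p505", "rd_p26", "rd_p01"])
    def test_same_dosage_segments_never_overlap(self, case, request):
        bundle = request.getfixturevalue(case)
        check_no_same_dosage_overlap(bundle.segments)

    def test_breakpoint_counts(self, rd_p01, rd_p26, chr21_length):
        # 13 SV rows -> 26 distinct boundaries
        assert count_case_breakpoints(rd_p01.segments, chr21_length) == 26
        # abutting rows share boundaries; lost telomeric ends are not junctions
        assert count_case_breakpoints(rd_p26.segments, chr21_length) == 8

    def test_single_deletion_and_empty(self):
        seg = Segment("A", GenomicInterval("chr21", 100, 200), Dosage.DEL)
        assert count_case_breakpoints([seg]) == 2
        assert count_case_breakpoints([]) == 0


class TestWalks:
    def test_derivative_adjacency_forward_and_inverted(self):
        a = WalkStep(GenomicInterval("c", 0, 10))
        b = WalkStep(GenomicInterval("c", 10, 20))
        assert derivative_adjacent(a, b)
        assert not derivative_adjacent(b, a)
        ai, bi = a.reverse(), b.reverse()
        assert derivative_adjacent(bi, ai)
        assert not derivative_adjacent(ai, bi)

    def test_normalized_merges_reference_runs(self):
        w = DerivativeWalk(
            [
                WalkStep(GenomicInterval("c", 0, 10)),
                WalkStep(GenomicInterval("c", 10, 20)),
                WalkStep(GenomicInterval("c", 5, 15), True),
            ]
        )
        n = w.normalized()
        assert len(n.steps) == 2
        assert n.steps[0].interval == GenomicInterval("c", 0, 20)

    def test_walk_equivalence_under_reflection_and_rotation(self):
        steps = [
            WalkStep(GenomicInterval("c", 0, 10)),
            WalkStep(GenomicInterval("c", 30, 40), True),
            WalkStep(GenomicInterval("c", 50, 60)),
        ]
        ring = DerivativeWalk(steps, circular=True)
        rotated = DerivativeWalk(steps[1:] + steps[:1], circular=True)
        assert ring.equivalent(rotated)
        assert ring.equivalent(ring.reversed())
        linear = DerivativeWalk(steps)
        assert linear.equivalent(linear.reversed())
        assert not linear.equivalent(ring)

    def test_validate_rejects_duplicate_novel_adjacency(self):
        jx = Junction.from_orientation("c", 10, 30, "HT")
        w = DerivativeWalk(
            [
                WalkStep(GenomicInterval("c", 0, 10)),
                WalkStep(GenomicInterval("c", 30, 40)),
                WalkStep(GenomicInterval("c", 50, 60)),
            ],
            novel_adjacencies=[jx, jx],
        )
        with pytest.raises(ValueError, match="twice"):
            w.validate()

    def test_validate_requires_junction_backing(self):
        w = DerivativeWalk(
            [
                WalkStep(GenomicInterval("c", 0, 10)),
                WalkStep(GenomicInterval("c", 30, 40)),
            ],
            novel_adjacencies=[],
        )
        w.validate()  # no junctions attached: structural check only
        w2 = DerivativeWalk(
            w.steps, novel_adjacencies=[Junction.from_orientation("c", 10, 30, "HT")]
        )
        w2.validate()


class TestJunctionOrientation:
    @pytest.mark.parametrize(
        "orientation, sides",
        [("HT", ("LEFT", "RIGHT")), ("HH", ("LEFT", "LEFT")),
         ("TT", ("RIGHT", "RIGHT")), ("TH", ("RIGHT", "LEFT"))],
    )
    def test_orientation_encodes_sides(self, orientation, sides):
        jx = Junction.from_orientation("c", 100, 200, orientation)
        assert (jx.bp1.side.value, jx.bp2.side.value) == sides
        assert jx.orientation == orientation

    def test_coordinate_sorting_tracks_derivative_order(self):
        from cgrkit.core import Breakpoint, Side

        jx = Junction(
            Breakpoint("c", 200, Side.LEFT), Breakpoint("c", 100, Side.RIGHT)
        )
        assert (jx.bp1.position, jx.bp2.position) == (100, 200)
        assert jx.swapped
        assert jx.orientation == "TH"  # tandem-duplication type
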