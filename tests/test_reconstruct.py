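"""Breakpoint-graph assembly: toy cases, oracle equivalence, round-trips."""

from itertools import permutations, product

import numpy as np
import pytest

from cgrkit.core import (
    DerivativeWalk,
    Dosage,
    GenomicInterval,
    Junction,
    Segment,
    Side,
    WalkStep,
    derivative_adjacent,
)
from cgrkit.reconstruct import (
    InconsistentEvidenceError,
    ReconstructionError,
    assemble_walk,
    build_graph,
    count_breakpoints,
    count_template_switches,
    detect_ring,
    graph_from_walk,
    junctions_from_walk,
)
from cgrkit.simulate import random_walk


def _seg(label, start, end, dosage, contig="c"):
    return Segment(label, GenomicInterval(contig, start, end), Dosage[dosage])


class TestBuildGraph:
    def test_tandem_duplication_toy_graph(self):
        segments = [
            _seg("A", 0, 100, "NML"),
            _seg("B", 100, 200, "NML"),
            _seg("C", 200, 300, "NML"),
        ]
        jx = Junction.from_orientation("c", 100, 200, "TH")
        graph = build_graph(segments, [jx], cn_per_segment={"B": 3})
        assert len(graph.junctions) == 1
        assert graph.copies == [1, 2, 1]

    def test_endpoint_off_boundary_rejected_at_zero_tolerance(self):
        segments = [_seg("A", 0, 1000, "NML"), _seg("B", 1000, 2000, "DUP")]
        jx = Junction.from_orientation("c", 999, 2000, "TH")
        with pytest.raises(ReconstructionError, match="nearest"):
            build_graph(segments, [jx], tolerance=0)
        graph = build_graph(segments, [jx], tolerance=1)
        assert graph.junctions[0].bp1.position == 1000  # snapped

    def test_gap_filling_between_segments(self):
        segments = [_seg("A", 100, 200, "DEL")]
        graph = build_graph(
            segments, [], region=GenomicInterval("c", 0, 400)
        )
        assert [a.start for a in graph.atoms] == [0, 100, 200]
        assert graph.copies == [1, 0, 1]


class TestAssembleWalk:
    def test_tandem_duplication_walk(self):
        segments = [
            _seg("A", 0, 100, "NML"),
            _seg("B", 100, 200, "DUP"),
            _seg("C", 200, 300, "NML"),
        ]
        jx = Junction.from_orientation("c", 100, 200, "TH")
        walks = assemble_walk(build_graph(segments, [jx]))
        expected = DerivativeWalk(
            [
                WalkStep(GenomicInterval("c", 0, 200)),
                WalkStep(GenomicInterval("c", 100, 300)),
            ]
        )
        assert len(walks) == 1
        assert walks[0].equivalent(expected)
        assert count_template_switches(walks[0]) == 1

    def test_reference_identical_walk_has_zero_switches(self):
        segments = [_seg("A", 0, 300, "NML")]
        walks = assemble_walk(build_graph(segments, []))
        assert count_template_switches(walks[0]) == 0
        assert not detect_ring(walks[0])[0]

    def test_inconsistent_evidence_reported(self):
        # a duplication with no junction backing it cannot be traversed
        segments = [_seg("A", 0, 100, "NML"), _seg("B", 100, 200, "DUP")]
        with pytest.raises(InconsistentEvidenceError, match="novel edges"):
            assemble_walk(build_graph(segments, []))

    def test_state_budget_enforced(self, rd_p01, chr21_length):
        from cgrkit.nomenclature import parse_seq, seq_to_walk

        w = seq_to_walk(parse_seq(rd_p01.karyotype_string), chr21_length)
        graph = graph_from_walk(w, chr21_length)
        with pytest.raises(ReconstructionError, match="budget"):
            assemble_walk(graph, max_states=50)


class TestCaseFixtures:
    def test_ring_case_reconstruction(self, rd_p26, chr21_length):
        """The ring case: a unique circular walk, the in-between segment
        inverted and relocated next to retained short-arm material."""
        from cgrkit.nomenclature import parse_seq, seq_to_walk

        truth = seq_to_walk(parse_seq(rd_p26.karyotype_string), chr21_length)
        walks = assemble_walk(graph_from_walk(truth, chr21_length))
        assert len(walks) == 1
        walk = walks[0]
        assert walk.circular
        assert walk.equivalent(truth)
        ring, summary = detect_ring(walk, rd_p26.segments)
        assert ring
        assert set(summary["lost_segments"]) == {"Tel", "B", "D", "F", "H"}

    def test_complex_cases_recover_printed_derivative(
        self, rd_p505, rd_p01, chr21_length
    ):
        from cgrkit.nomenclature import parse_seq, seq_to_walk

        for bundle, n_junctions in ((rd_p505, 9), (rd_p01, 15)):
            truth = seq_to_walk(parse_seq(bundle.karyotype_string), chr21_length)
            walks = assemble_walk(graph_from_walk(truth, chr21_length))
            matches = [w for w in walks if w.equivalent(truth)]
            assert matches, bundle.case_id
            assert matches[0].junction_count() == n_junctions

    def test_duplication_case_cassette_order(self, rd_p505, chr21_length):
        """The three-segment cassette appears as consecutive steps D, J,
        F-inverted in the derivative."""
        from cgrkit.nomenclature import parse_seq, seq_to_walk

        truth = seq_to_walk(parse_seq(rd_p505.karyotype_string), chr21_length)
        walks = assemble_walk(graph_from_walk(truth, chr21_length))
        segs = {s.label: s.interval for s in rd_p505.segments}
        expected = [
            (segs["D"].start, segs["D"].end, False),
            (segs["J"].start, segs["J"].end, False),
            (segs["F"].start, segs["F"].end, True),
        ]

        def has_cassette(walk):
            tup = [
                (s.interval.start, s.interval.end, s.inverted)
                for s in walk.normalized().steps
                if not s.is_gap
            ]
            return any(
                tup[i : i + 3] == expected for i in range(len(tup) - 2)
            )

        assert any(has_cassette(w) for w in walks)


class TestBreakpointCounting:
    def test_complex_case(self, rd_p01, chr21_length):
        assert count_breakpoints(rd_p01.segments, chr21_length) == 26

    def test_trivial_cases(self):
        assert count_breakpoints([_seg("A", 10, 20, "DEL")]) == 2
        assert count_breakpoints([]) == 0


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------

def _step_exit(atom, inverted):
    return (atom.start, Side.RIGHT) if inverted else (atom.end, Side.LEFT)


def _step_entry(atom, inverted):
    return (atom.end, Side.LEFT) if inverted else (atom.start, Side.RIGHT)


def brute_force_walks(graph):
    """Enumerate every constraint-satisfying walk by raw permutation.

    Independent of the DFS: lists all orderings/orientations of the atom
    copy multiset, then checks each join against the reference adjacency
    or the novel-edge multiset.  Returns canonical walk keys for linear
    and circular solutions.
    """
    items = []
    for i, c in enumerate(graph.copies):
        items += [i] * c
    edge_pairs = []
    for d1, d2 in graph.endpoints:
        assert d1[0] == d2[0] == "boundary"
        edge_pairs.append(frozenset([(d1[1], d1[2]), (d2[1], d2[2])])
                          if (d1[1], d1[2]) != (d2[1], d2[2])
                          else frozenset([(d1[1], d1[2])]))

    found = set()
    for perm in set(permutations(items)):
        for orient in product([False, True], repeat=len(perm)):
            steps = [WalkStep(graph.atoms[i], inv) for i, inv in zip(perm, orient)]
            for circular in (False, True):
                joins = list(zip(range(len(steps) - 1), range(1, len(steps))))
                if circular:
                    if len(steps) < 2:
                        continue
                    joins.append((len(steps) - 1, 0))
                needed = []
                ok = True
                for i, j in joins:
                    if derivative_adjacent(steps[i], steps[j]):
                        continue
                    a = _step_exit(graph.atoms[perm[i]], orient[i])
                    b = _step_entry(graph.atoms[perm[j]], orient[j])
                    needed.append(frozenset([a, b]) if a != b else frozenset([a]))
                    if needed.count(needed[-1]) > edge_pairs.count(needed[-1]):
                        ok = False
                        break
                if not ok or sorted(needed, key=sorted) != sorted(
                    edge_pairs, key=sorted
                ):
                    continue
                walk = DerivativeWalk(list(steps), circular=circular)
                found.add(walk.canonical()._key() + (circular,))
    return found


class TestOracleEquivalence:
    def test_dfs_matches_brute_force_on_random_small_graphs(self):
        """Exhaustive DFS output equals raw permutation enumeration."""
        rng = np.random.default_rng(42)
        n_compared = 0
        while n_compared < 25:
            walk = random_walk(
                rng, contig_length=20_000, max_events=2, unit=1000
            )
            graph = graph_from_walk(walk, 20_000)
            if sum(graph.copies) > 6 or len(graph.junctions) > 4:
                continue
            dfs = {
                w.canonical()._key() + (w.circular,)
                for w in assemble_walk(graph)
            }
            assert dfs == brute_force_walks(graph)
            n_compared += 1


class TestSimulationRoundTrip:
    def test_truth_walk_recovered_from_extracted_evidence(self):
        """simulate -> extract junctions + copy numbers -> rebuild graph ->
        assemble recovers the simulated walk (100 seeded scenarios)."""
        rng = np.random.default_rng(20240922)
        recovered = 0
        for _ in range(100):
            walk = random_walk(rng, contig_length=50_000, max_events=3)
            graph = graph_from_walk(walk, 50_000)
            try:
                walks = assemble_walk(graph, max_states=200_000)
            except ReconstructionError:  # pathological ambiguity blow-up
                continue
            assert any(w.equivalent(walk) for w in walks)
            recovered += 1
        assert recovered >= 95

    def test_conservation_of_copies_and_edges(self):
        """Every returned walk visits each atom exactly its copy count and
        uses each novel edge exactly once."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            walk = random_walk(rng, contig_length=30_000, max_events=3)
            graph = graph_from_walk(walk, 30_000)
            for w in assemble_walk(graph, max_states=200_000):
                visits = {i: 0 for i in range(len(graph.atoms))}
                for s in w.steps:
                    if s.is_gap:
                        continue
                    for i, atom in enumerate(graph.atoms):
                        if atom == s.interval:
                            visits[i] += 1
                assert [visits[i] for i in sorted(visits)] == graph.copies
                assert len(w.novel_adjacencies) == w.junction_count()
                assert len({id(j) for j in w.novel_adjacencies}) == len(
                    w.novel_adjacencies
                )

    def test_gap_walk_round_trip(self):
        """An unresolved junction partner survives extraction and assembly
        as an explicit gap with its anchor coordinate."""
        contig = "c"
        walk = DerivativeWalk(
            [
                WalkStep(GenomicInterval(contig, 0, 10_000)),
                WalkStep(None, anchor=2_001),
                WalkStep(GenomicInterval(contig, 15_000, 30_000)),
            ]
        )
        graph = graph_from_walk(walk, 30_000)
        walks = assemble_walk(graph)
        assert len(walks) == 1
        got = walks[0]
        assert got.gaps == [1]
        assert got.steps[1].anchor == 2_001
        assert got.equivalent(walk)
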