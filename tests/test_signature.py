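"""Microhomology and insertion classification against independent oracles."""

import numpy as np
import pytest

from cgrkit.core import DerivativeWalk, GenomicInterval, WalkStep
from cgrkit.signature import (
    InsertionOrigin,
    Mechanism,
    call_mechanism,
    classify_insertion,
    classify_junction,
    is_simple_repeat,
    junction_flanks,
    microhomology,
    revcomp,
)
from cgrkit.simulate import JunctionPlan, make_reference, simulate_derivative


def oracle_microhomology(fa: str, fb: str, ba: str, bb: str) -> int:
    """Brute force: enumerate every breakpoint placement.

    A placement shifted d bases right of the nominal cut is valid when
    the d bases after the cut match the reference continuation past
    breakpoint 1 (and symmetrically to the left).  The microhomology is
    the number of valid placements minus one.
    """
    valid = 0
    for d in range(-len(fa), len(fb) + 1):
        if d >= 0:
            ok = d <= len(ba) and fb[:d] == ba[:d]
        else:
            k = -d
            ok = k <= len(bb) and fa[len(fa) - k :] == bb[len(bb) - k :]
        if ok:
            valid += 1
    return valid - 1


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _make_junction_seqs(rng, m, w=150):
    """Random flank quadruple with exactly m nt of planted homology."""
    left = int(rng.integers(0, m + 1))
    right = m - left
    fb = _rand_seq(rng, w)
    ba = fb[:right] + _diff(rng, fb[right]) + _rand_seq(rng, w - right - 1)
    bb = _rand_seq(rng, w)
    fa = _rand_seq(rng, w - left - 1) + _diff(rng, bb[-(left + 1)]) + bb[w - left :]
    return fa, fb, ba, bb


def _diff(rng, base):
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(3))]


class TestMicrohomology:
    def test_worked_example(self):
        """Flanks ...GATCCA / CCAGTT with the reference continuing CCA...
        share 3 junction bases."""
        fa = "GGGGGGATCCA"
        fb = "CCAGTTTTTTT"
        ba = "CCATAAAAAAA"  # continues like the incoming flank for 3 nt
        bb = "TTTTTTTTTTG"  # no homology on the left side
        assert microhomology(fa, fb, ba, bb) == 3
        assert oracle_microhomology(fa, fb, ba, bb) == 3

    def test_dissimilar_flanks_are_blunt(self):
        assert microhomology("AAAA", "CCCC", "GGGG", "TTTT") == 0

    def test_long_terminal_repeat(self):
        rng = np.random.default_rng(3)
        fa, fb, ba, bb = _make_junction_seqs(rng, 79)
        assert microhomology(fa, fb, ba, bb) == 79

    def test_lowercase_rejected(self):
        with pytest.raises(ValueError):
            microhomology("acgt", "ACGT", "ACGT", "ACGT")

    def test_n_runs_flagged(self):
        with pytest.warns(UserWarning, match="non-N"):
            microhomology("AANN", "NNCC", "GGGG", "TTTT")

    def test_equals_oracle_on_1000_random_junctions(self):
        """Property: the two-run computation equals full placement
        enumeration for 1,000 random junction constructions."""
        rng = np.random.default_rng(20240923)
        for _ in range(1000):
            m = int(rng.integers(0, 80))
            fa, fb, ba, bb = _make_junction_seqs(rng, m)
            got = microhomology(fa, fb, ba, bb)
            assert got == m
            assert got == oracle_microhomology(fa, fb, ba, bb)


class TestPlantedRecovery:
    def test_every_homology_length_recovered_exactly(self):
        """Simulated junctions with m in {0..79} come back with exactly m."""
        contig = "t"
        walk = DerivativeWalk(
            [
                WalkStep(GenomicInterval(contig, 0, 4000)),
                WalkStep(GenomicInterval(contig, 6000, 10_000)),
            ]
        )
        reference = make_reference(10_000, seed=9)
        for m in range(80):
            sim = simulate_derivative(
                reference, walk, [JunctionPlan(microhomology=m)],
                contig=contig, seed=m,
            )
            (jx,) = sim.junctions
            fa, fb, ba, bb = junction_flanks(jx, {contig: sim.reference})
            assert microhomology(fa, fb, ba, bb) == m


class TestClassifyInsertion:
    @pytest.fixture()
    def rng(self):
        return np.random.default_rng(77)

    def test_no_inserted_bases(self, rng):
        fa, fb = _rand_seq(rng, 150), _rand_seq(rng, 150)
        call = classify_insertion(fa + fb, fa, fb, [("w", _rand_seq(rng, 2000))])
        assert call.origin == InsertionOrigin.NONE and call.length == 0

    def test_short_nontemplated_insert(self, rng):
        fa, fb = _rand_seq(rng, 150), _rand_seq(rng, 150)
        call = classify_insertion(
            fa + "TTAC" + fb, fa, fb, [("w", _rand_seq(rng, 2000))]
        )
        assert call.origin == InsertionOrigin.NONTEMPLATED
        assert call.length == 4 and call.seq == "TTAC"

    def test_templated_insert_found_in_window(self, rng):
        window = _rand_seq(rng, 2000)
        ins = window[300:340]
        fa, fb = _rand_seq(rng, 150), _rand_seq(rng, 150)
        call = classify_insertion(fa + ins + fb, fa, fb, [("near_bp1", window)])
        assert call.origin == InsertionOrigin.TEMPLATED
        assert call.identity == 1.0 and call.locus == "near_bp1"

    def test_flanks_must_span_the_join(self, rng):
        fa, fb = _rand_seq(rng, 150), _rand_seq(rng, 150)
        with pytest.raises(ValueError, match="span"):
            classify_insertion(_rand_seq(rng, 400), fa, fb, [])

    def test_false_positive_rate_below_one_percent(self):
        """Random inserts far from both windows are essentially never
        called TEMPLATED (<1% over 1,000 trials)."""
        rng = np.random.default_rng(20240924)
        fp = 0
        for _ in range(1000):
            fa, fb = _rand_seq(rng, 60), _rand_seq(rng, 60)
            ins = _rand_seq(rng, int(rng.integers(10, 50)))
            windows = [("a", _rand_seq(rng, 2000)), ("b", _rand_seq(rng, 2000))]
            call = classify_insertion(fa + ins + fb, fa, fb, windows)
            if call.origin == InsertionOrigin.TEMPLATED:
                fp += 1
        assert fp < 10

    def test_simple_repeat_detection(self):
        assert is_simple_repeat("AAAAAAAA")
        assert is_simple_repeat("ATATATATAT")
        assert not is_simple_repeat("ACGTGTCAGT")


class TestScenarioSignatures:
    def test_planted_values_recovered_in_all_scenarios(self, scenarios):
        """Noise-free scenario junctions return the exact planted
        microhomology and insert lengths, with correct origin calls."""
        for name, res in scenarios.items():
            sim = res["sim"]
            reference = {sim.contig: sim.reference}
            for jx, plan in zip(sim.junctions, sim.junction_plans):
                if plan is None or not jx.resolved or jx.junction_seq is None:
                    continue
                sig = classify_junction(jx, reference)
                if plan.insertion is None:
                    assert sig.microhomology_len == plan.microhomology, (name, jx.id)
                    assert sig.insertion_len == 0
                else:
                    assert sig.insertion_len == plan.insertion.length, (name, jx.id)
                    expected = (
                        InsertionOrigin.TEMPLATED
                        if plan.insertion.origin == "templated"
                        else InsertionOrigin.NONTEMPLATED
                    )
                    assert sig.insertion_origin == expected
                    if plan.insertion.inverted:
                        assert "short_inversion" in sig.flags

    def test_blunt_definition(self, scenarios):
        sim = scenarios["ring21"]["sim"]
        reference = {sim.contig: sim.reference}
        sigs = {
            jx.id: classify_junction(jx, reference)
            for jx in sim.junctions
            if jx.junction_seq is not None
        }
        blunt = [jid for jid, s in sigs.items() if s.blunt]
        assert blunt == ["J3"]  # the planted blunt join, and only it


class TestMechanism:
    def test_replicative_call_for_gain_rich_case(self, scenarios):
        res = scenarios["chromoanasynthesis_dup6"]
        sim = res["sim"]
        reference = {sim.contig: sim.reference}
        sigs = [
            classify_junction(jx, reference)
            for jx in sim.junctions
            if jx.junction_seq is not None
        ]
        call = call_mechanism(sigs, sim.walk)
        assert call.call == Mechanism.CHROMOANASYNTHESIS
        assert call.evidence

    def test_ring_topology_call(self, scenarios):
        sim = scenarios["ring21"]["sim"]
        call = call_mechanism([], sim.walk)
        assert call.call == Mechanism.ALU_MEDIATED_RING

    def test_single_blunt_deletion_is_end_joining(self):
        walk = DerivativeWalk(
            [
                WalkStep(GenomicInterval("c", 0, 1000)),
                WalkStep(GenomicInterval("c", 2000, 5000)),
            ]
        )
        from cgrkit.signature import JunctionSignature

        sig = JunctionSignature("j1", microhomology_len=0)
        call = call_mechanism([sig], walk)
        assert call.call == Mechanism.SIMPLE_NHEJ_LIKE

    def test_unclassified_fallback(self):
        walk = DerivativeWalk(
            [
                WalkStep(GenomicInterval("c", 0, 1000)),
                WalkStep(GenomicInterval("c", 3000, 4000), True),
                WalkStep(GenomicInterval("c", 2000, 2500)),
                WalkStep(GenomicInterval("c", 4500, 5000)),
            ]
        )
        from cgrkit.signature import JunctionSignature

        sigs = [JunctionSignature(f"j{i}", microhomology_len=40) for i in range(3)]
        call = call_mechanism(sigs, walk)
        assert call.call == Mechanism.UNCLASSIFIED


class TestRevcomp:
    def test_involution(self):
        assert revcomp(revcomp("ACGTTN")) == "ACGTTN"
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AAC") == "GTT"
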