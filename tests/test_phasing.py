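"""Parental-origin phasing: fractions, test statistics, origin calls."""

import math

import numpy as np
import pandas as pd
import pytest

from cgrkit.core import Dosage, GenomicInterval, Segment
from cgrkit.io import read_phased_snvs
from cgrkit.phasing import (
    PhasingResult,
    call_origin,
    origin_test,
    run_phasing,
    segment_allele_fractions,
)
from cgrkit.simulate import simulate_trio_snvs


def _seg(label, start, end, dosage):
    return Segment(label, GenomicInterval("c", start, end), Dosage[dosage])


def _sites(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "qual",
            "child_gt",
            "father_gt",
            "mother_gt",
            "child_ad",
            "alt_parent",
        ],
    )


def _row(pos, child, father, mother, ad=None, alt_parent=None):
    return {
        "contig": "c",
        "pos": pos,
        "qual": 60.0,
        "child_gt": child,
        "father_gt": father,
        "mother_gt": mother,
        "child_ad": ad,
        "alt_parent": alt_parent,
    }


class TestSegmentFractions:
    def test_deleted_segment_tallies_remaining_allele(self):
        """All remaining alleles maternal -> the deletion sits on the
        paternal homolog (maternal fraction 1.0)."""
        rows = [
            _row(p, (1, 1), (0, 0), (1, 1)) for p in range(10, 60, 10)
        ]
        segs = [_seg("D", 0, 100, "DEL")]
        (sf,) = segment_allele_fractions(_sites(rows), segs)
        assert sf.maternal_fraction == 1.0
        assert sf.paternal_fraction == 0.0
        assert sf.n_informative == 5

    def test_balanced_diploid_segment(self):
        rows = [
            _row(p, (0, 1), (1, 1), (0, 0), alt_parent="paternal")
            for p in range(10, 60, 10)
        ] + [
            _row(p, (0, 1), (0, 0), (1, 1), alt_parent="maternal")
            for p in range(60, 110, 10)
        ]
        (sf,) = segment_allele_fractions(_sites(rows), [_seg("N", 0, 200, "NML")])
        assert sf.paternal_fraction == pytest.approx(0.5)

    def test_duplication_allele_dosage_sharpens_to_two_thirds(self):
        """CN=3 with the paternal haplotype doubled: paternal-informative
        ALT at depth fraction 2/3, maternal-informative at 1/3."""
        rows = [
            _row(10, (0, 1), (1, 1), (0, 0), ad=(10, 20), alt_parent="paternal"),
            _row(20, (0, 1), (0, 0), (1, 1), ad=(20, 10), alt_parent="maternal"),
        ]
        (sf,) = segment_allele_fractions(
            _sites(rows), [_seg("B", 0, 100, "DUP")], use_allelic_depth=True
        )
        assert sf.paternal_fraction == pytest.approx(2 / 3)

    def test_segment_without_sites_excluded(self):
        (sf,) = segment_allele_fractions(_sites([]), [_seg("Z", 0, 100, "NML")])
        assert sf.n_informative == 0
        assert sf.paternal_fraction is None


class TestOriginTest:
    def test_identical_groups_give_t0_p1(self):
        assert origin_test([0.5, 0.5], [0.5, 0.5]) == (0.0, 1.0)

    def test_requires_two_segments_per_group(self):
        with pytest.raises(ValueError, match="at least 2"):
            origin_test([0.6], [0.5, 0.5])

    def test_separated_groups_are_significant(self):
        t, p = origin_test([0.66, 0.67, 0.65, 0.66], [0.5, 0.51, 0.49, 0.5])
        assert p < 1e-4 and t > 0


class TestCallOrigin:
    def test_nonsignificant_p_is_inconclusive(self):
        res = PhasingResult("x", [], t=1.0, p=0.5, delta=0.2)
        assert call_origin(res) == "INCONCLUSIVE"

    def test_tiny_effect_is_inconclusive_despite_significance(self):
        res = PhasingResult("x", [], t=5.0, p=1e-4, delta=0.01)
        assert call_origin(res) == "INCONCLUSIVE"

    def test_directions(self):
        assert call_origin(PhasingResult("x", [], p=1e-4, delta=0.2)) == "PATERNAL"
        assert call_origin(PhasingResult("x", [], p=1e-4, delta=-0.2)) == "MATERNAL"


class TestEndToEnd:
    def _run(self, tmp_path, dosages, origin, seed, relabel=None, ad=True):
        segments = [
            _seg(chr(65 + i), i * 5000, i * 5000 + 4000, d)
            for i, d in enumerate(dosages)
        ]
        segments = [
            Segment(s.label, GenomicInterval("chr21_toy", s.interval.start,
                                             s.interval.end), s.dosage)
            for s in segments
        ]
        out = simulate_trio_snvs(
            "chr21_toy", 5000 * len(dosages), segments, origin,
            sites_per_segment=200, seed=seed, outdir=tmp_path / str(seed),
        )
        d = tmp_path / str(seed)
        sites = read_phased_snvs(d / "child.vcf", d / "father.vcf", d / "mother.vcf")
        analyzed = segments if relabel is None else relabel(segments)
        return run_phasing(sites, analyzed, use_allelic_depth=ad)

    def test_paternal_duplication_recovered(self, tmp_path):
        dosages = ["DUP", "NML"] * 3
        res = self._run(tmp_path, dosages, "paternal", seed=1)
        assert res.origin_call == "PATERNAL"
        assert res.p < 0.05

    def test_maternal_deletion_recovered(self, tmp_path):
        """Remaining alleles paternal -> deletions on the maternal homolog."""
        dosages = ["DEL", "NML", "DEL", "NML", "NML"]
        res = self._run(tmp_path, dosages, "maternal", seed=2, ad=False)
        assert res.origin_call == "MATERNAL"

    def test_single_affected_segment_is_inconclusive(self, tmp_path):
        dosages = ["DUP", "NML", "NML"]
        res = self._run(tmp_path, dosages, "paternal", seed=3)
        assert res.origin_call == "INCONCLUSIVE"
        assert "insufficient" in res.note

    def test_balanced_control_stays_inconclusive(self, tmp_path):
        """A false candidate CGR over copy-neutral segments: fractions near
        0.5, no origin call."""

        def relabel(segments):
            return [
                Segment(s.label, s.interval,
                        Dosage.DUP if i % 2 == 0 else Dosage.NML)
                for i, s in enumerate(segments)
            ]

        dosages = ["NML"] * 8
        res = self._run(tmp_path, dosages, "paternal", seed=4, relabel=relabel)
        assert res.origin_call == "INCONCLUSIVE"
        for sf in res.per_segment:
            se = 0.5 / math.sqrt(sf.n_informative)
            assert abs(sf.paternal_fraction - 0.5) < 5 * se
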