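"""Parental origin of the rearranged allele from trio SNV genotypes.

For every copy-number segment the fraction of phase-informative sites
whose child-carried allele is paternal vs maternal is computed.  In
unaffected diploid segments both fractions sit near 0.5.  A deletion
removes one parental homolog, so the remaining alleles trace to the
*other* parent: a deletion whose informative alleles are mostly maternal
arose on the paternal homolog.  A duplication adds a copy of the carrier
parent's haplotype; at the genotype level this is invisible, but with
read-level allelic depths the carrier parent's allele sits at dosage 2/3
(two copies of three), which is the default signal used here when AD is
available.

The origin call compares per-segment paternal-support values between
affected (DEL/DUP) and control (diploid) segments with a Welch two-sided
t-test.  A call additionally requires the group difference to exceed a
minimal biological effect (default 0.05): the smallest real dosage
effect is 1/6, so a statistically significant sub-percent shift carries
no biological meaning and stays INCONCLUSIVE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Dosage, Segment

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_EFFECT = 0.05

_AFFECTED = {Dosage.DEL, Dosage.TELDEL, Dosage.DUP}


@dataclass
class SegmentFractions:
    label: str
    dosage: Dosage
    n_informative: int
    paternal_fraction: Optional[float]
    maternal_fraction: Optional[float]


@dataclass
class PhasingResult:
    case_id: str
    per_segment: list
    t: Optional[float] = None
    p: Optional[float] = None
    #: mean paternal-support difference, affected minus control
    delta: Optional[float] = None
    group_sizes: tuple = (0, 0)
    origin_call: str = "INCONCLUSIVE"
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "per_segment": [
                {
                    "label": s.label,
                    "dosage": s.dosage.value,
                    "n_informative": s.n_informative,
                    "paternal_fraction": s.paternal_fraction,
                    "maternal_fraction": s.maternal_fraction,
                }
                for s in self.per_segment
            ],
            "t": self.t,
            "p": self.p,
            "delta": self.delta,
            "group_sizes": list(self.group_sizes),
            "origin_call": self.origin_call,
            "note": self.note,
        }


def _hemizygous_parent(child_gt, father_gt, mother_gt) -> Optional[str]:
    """Parent of the single remaining allele in a deleted segment.

    The child appears homozygous; the allele is attributed to whichever
    parent alone carries it.
    """
    if None in (child_gt, father_gt, mother_gt):
        return None
    alleles = set(child_gt)
    if len(alleles) != 1:
        return None  # apparent het inside a deletion: not interpretable
    a = alleles.pop()
    f_has, m_has = a in father_gt, a in mother_gt
    if f_has and not m_has:
        return "paternal"
    if m_has and not f_has:
        return "maternal"
    return None


def segment_allele_fractions(
    sites: pd.DataFrame,
    segments: Sequence[Segment],
    use_allelic_depth: bool = False,
) -> list[SegmentFractions]:
    """Per-segment parental allele fractions from annotated trio sites.

    Hemizygous (DEL/TELDEL) segments tally the single remaining allele's
    parent.  Diploid and duplicated segments use the diploid ALT-parent
    annotation; with ``use_allelic_depth`` each site contributes its
    child allele-dosage (sharpening a CN=3 duplication to 2/3) instead of
    a 0/1 count.  Segments without informative sites report null
    fractions and are excluded from downstream testing.
    """
    out: list[SegmentFractions] = []
    for seg in segments:
        iv = seg.interval
        sel = sites[
            (sites["contig"] == iv.contig)
            & (sites["pos"] >= iv.start + 1)
            & (sites["pos"] <= iv.end)
        ]
        weights: list[float] = []
        if seg.dosage in (Dosage.DEL, Dosage.TELDEL):
            for _, row in sel.iterrows():
                parent = _hemizygous_parent(
                    row["child_gt"], row["father_gt"], row["mother_gt"]
                )
                if parent is not None:
                    weights.append(1.0 if parent == "paternal" else 0.0)
        else:
            informative = sel[sel["alt_parent"].notna()]
            for _, row in informative.iterrows():
                pat_is_alt = row["alt_parent"] == "paternal"
                if use_allelic_depth and row["child_ad"] is not None:
                    ad = row["child_ad"]
                    total = ad[0] + ad[1]
                    if total == 0:
                        continue
                    alt_frac = ad[1] / total
                    weights.append(alt_frac if pat_is_alt else 1.0 - alt_frac)
                else:
                    weights.append(1.0 if pat_is_alt else 0.0)
        n = len(weights)
        if n == 0:
            out.append(SegmentFractions(seg.label, seg.dosage, 0, None, None))
        else:
            pat = float(np.mean(weights))
            out.append(SegmentFractions(seg.label, seg.dosage, n, pat, 1.0 - pat))
    return out


def origin_test(
    affected_fractions: Sequence[float], control_fractions: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample two-sided t-test on per-segment fractions."""
    a = np.asarray(affected_fractions, dtype=float)
    b = np.asarray(control_fractions, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 segments per group for the t-test")
    if np.var(a) == 0 and np.var(b) == 0:
        if math.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def call_origin(
    result: PhasingResult,
    alpha: float = DEFAULT_ALPHA,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> str:
    """Origin label from a completed test (fields set by :func:`run_phasing`).

    PATERNAL when the affected segments' paternal-support exceeds the
    control mean by at least ``min_effect`` at significance ``alpha``
    (MATERNAL symmetric); everything else is INCONCLUSIVE.
    """
    if result.p is None:
        return "INCONCLUSIVE"
    return _decide(result.delta, result.p, alpha, min_effect)


def _decide(delta: Optional[float], p: float, alpha: float, min_effect: float) -> str:
    if delta is None or p >= alpha or abs(delta) < min_effect:
        return "INCONCLUSIVE"
    return "PATERNAL" if delta > 0 else "MATERNAL"


def run_phasing(
    sites: pd.DataFrame,
    segments: Sequence[Segment],
    case_id: str = "",
    alpha: float = DEFAULT_ALPHA,
    min_effect: float = DEFAULT_MIN_EFFECT,
    use_allelic_depth: bool = False,
) -> PhasingResult:
    """Full per-case phasing: fractions, Welch test, origin call.

    Affected segments contribute their *paternal-support*: the paternal
    fraction for duplications, the maternal fraction for deletions (the
    remaining allele's parent is the unaffected homolog).  Controls are
    the diploid segments' paternal fractions (baseline 0.5).
    """
    fractions = segment_allele_fractions(sites, segments, use_allelic_depth)
    result = PhasingResult(case_id=case_id, per_segment=fractions)

    support: list[float] = []
    control: list[float] = []
    for sf in fractions:
        if sf.paternal_fraction is None:
            continue
        if sf.dosage in (Dosage.DEL, Dosage.TELDEL):
            support.append(sf.maternal_fraction)
        elif sf.dosage == Dosage.DUP:
            support.append(sf.paternal_fraction)
        else:
            control.append(sf.paternal_fraction)
    result.group_sizes = (len(support), len(control))
    if len(support) < 2 or len(control) < 2:
        result.note = (
            f"insufficient segments for the test (affected {len(support)}, "
            f"control {len(control)}); need >=2 per group"
        )
        return result

    t, p = origin_test(support, control)
    result.t, result.p = t, p
    result.delta = float(np.mean(support) - np.mean(control))
    result.note = f"paternal-support delta {result.delta:+.3f}"
    result.origin_call = _decide(result.delta, p, alpha, min_effect)
    return result


__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_EFFECT",
    "SegmentFractions",
    "PhasingResult",
    "segment_allele_fractions",
    "origin_test",
    "call_origin",
    "run_phasing",
]
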