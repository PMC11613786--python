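"""Junction microarchitecture: microhomology, insertions, mechanism calls.

A junction joins two breakpoint flanks in derivative orientation.  The
*microhomology* of a junction is the number of junction-flanking bases
identical in both reference copies — the window within which the true
breakpoint cannot be placed.  With the derivative-oriented sequences

* ``flank_a``      — ends at breakpoint 1 (the sequence the derivative keeps),
* ``ref_beyond_a`` — how the reference continues past breakpoint 1,
* ``flank_b``      — starts at breakpoint 2,
* ``ref_beyond_b`` — how the reference runs up to breakpoint 2,

the microhomology is ``k_left + k_right`` where ``k_right`` is the length
of the common prefix of (``flank_b``, ``ref_beyond_a``) and ``k_left``
the common suffix of (``flank_a``, ``ref_beyond_b``).

Inserted bases at a junction are classified as TEMPLATED when they align
at >=90% identity over >=10 nt inside a +/-2 kb window around either
breakpoint (directly or reverse-complemented), else NONTEMPLATED.  When
both an insert and flanking homology could describe a join, the insert
takes precedence as the category; microhomology is still computed on the
insert-excised flanks.  ``blunt`` means no microhomology and no insert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import edlib

from .core import DerivativeWalk, Junction, Side

DEFAULT_FLANK_WINDOW = 150
DEFAULT_SEARCH_WINDOW = 2000
DEFAULT_MIN_TEMPLATED_LEN = 10
DEFAULT_MIN_TEMPLATED_IDENTITY = 0.90

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            break
        n += 1
    return n


def microhomology(
    flank_a: str, flank_b: str, ref_beyond_a: str, ref_beyond_b: str
) -> int:
    """Junction microhomology in nucleotides (0 for dissimilar flanks).

    All sequences are derivative-oriented uppercase ACGTN.  ``N`` runs at
    the junction truncate the comparison (computed on the non-N part,
    with a warning).
    """
    seqs = (flank_a, flank_b, ref_beyond_a, ref_beyond_b)
    for s in seqs:
        if not set(s) <= set("ACGTN"):
            raise ValueError("sequences must be uppercase ACGTN")
    k_right = _common_prefix(flank_b, ref_beyond_a)
    k_left = _common_prefix(flank_a[::-1], ref_beyond_b[::-1])
    junction_zone = flank_b[: k_right + 1] + flank_a[-(k_left + 1):]
    if "N" in junction_zone:
        warnings.warn(
            "N bases at the junction; microhomology computed on the non-N part",
            stacklevel=2,
        )
    return k_left + k_right


class InsertionOrigin(str, Enum):
    NONE = "NONE"
    NONTEMPLATED = "NONTEMPLATED"
    TEMPLATED = "TEMPLATED"


@dataclass
class InsertionCall:
    seq: str = ""
    length: int = 0
    origin: InsertionOrigin = InsertionOrigin.NONE
    locus: Optional[str] = None
    identity: Optional[float] = None
    inverted: bool = False


def _best_window_hit(insert: str, windows: Sequence[tuple[str, str]]):
    """Best (identity, locus, inverted) alignment of the insert in windows."""
    best = (0.0, None, False)
    for query, inverted in ((insert, False), (revcomp(insert), True)):
        for name, wseq in windows:
            if not wseq:
                continue
            res = edlib.align(query, wseq, mode="HW", task="distance")
            dist = res["editDistance"]
            if dist < 0:
                continue
            identity = 1.0 - dist / len(query)
            if identity > best[0]:
                best = (identity, name, inverted)
    return best


def classify_insertion(
    junction_seq: str,
    flank_a: str,
    flank_b: str,
    search_windows: Sequence[tuple[str, str]],
    min_templated_len: int = DEFAULT_MIN_TEMPLATED_LEN,
    min_templated_identity: float = DEFAULT_MIN_TEMPLATED_IDENTITY,
    anchor_len: int = 20,
) -> InsertionCall:
    """Extract and classify the inserted bases of a junction.

    ``junction_seq`` must span the join in derivative orientation;
    ``search_windows`` are (name, sequence) reference windows around the
    two breakpoints.  Raises if the flanks cannot be located in the
    junction sequence.
    """
    k = min(anchor_len, len(flank_a), len(flank_b))
    if k == 0:
        raise ValueError("empty flank")
    anchor_a, anchor_b = flank_a[-k:], flank_b[:k]
    ia = junction_seq.find(anchor_a)
    if ia < 0:
        raise ValueError("junction sequence does not span the join (flank A absent)")
    ib = junction_seq.find(anchor_b, ia + k)
    if ib < 0:
        raise ValueError("junction sequence does not span the join (flank B absent)")
    insert = junction_seq[ia + k : ib]
    if not insert:
        return InsertionCall()
    identity, locus, inverted = _best_window_hit(insert, search_windows)
    # "min match" counts matched bases: length minus the edit distance
    n_matched = len(insert) - round((1.0 - identity) * len(insert))
    if n_matched >= min_templated_len and identity >= min_templated_identity:
        return InsertionCall(
            insert, len(insert), InsertionOrigin.TEMPLATED, locus, identity, inverted
        )
    return InsertionCall(insert, len(insert), InsertionOrigin.NONTEMPLATED)


def is_simple_repeat(seq: str, max_period: int = 6, min_cover: float = 0.9) -> bool:
    """Homopolymer / short-tandem-repeat test for inserted bases."""
    if len(seq) < 4:
        return False
    for period in range(1, min(max_period, len(seq) // 2) + 1):
        unit = seq[:period]
        rep = (unit * (len(seq) // period + 1))[: len(seq)]
        matches = sum(1 for a, b in zip(seq, rep) if a == b)
        if matches / len(seq) >= min_cover:
            return True
    return False


@dataclass
class JunctionSignature:
    """Classification of one junction's microarchitecture."""

    junction_id: str
    microhomology_len: int = 0
    insertion_seq: Optional[str] = None
    insertion_len: int = 0
    insertion_origin: InsertionOrigin = InsertionOrigin.NONE
    templated_locus: Optional[str] = None
    templated_identity: Optional[float] = None
    flags: list = field(default_factory=list)

    @property
    def blunt(self) -> bool:
        return self.microhomology_len == 0 and self.insertion_len == 0

    def to_dict(self) -> dict:
        return {
            "junction_id": self.junction_id,
            "microhomology_len": self.microhomology_len,
            "insertion_len": self.insertion_len,
            "insertion_seq": self.insertion_seq,
            "insertion_origin": self.insertion_origin.value,
            "templated_locus": self.templated_locus,
            "templated_identity": self.templated_identity,
            "blunt": self.blunt,
            "flags": list(self.flags),
        }


# --------------------------------------------------------------------------
# flank extraction from the reference
# --------------------------------------------------------------------------

def _first_endpoint_flanks(ref: str, bp, w: int) -> tuple[str, str]:
    p = bp.position
    if bp.side == Side.LEFT:
        return ref[max(0, p - w): p], ref[p: p + w]
    return revcomp(ref[p: p + w]), revcomp(ref[max(0, p - w): p])


def _second_endpoint_flanks(ref: str, bp, w: int) -> tuple[str, str]:
    p = bp.position
    if bp.side == Side.RIGHT:
        return ref[p: p + w], ref[max(0, p - w): p]
    return revcomp(ref[max(0, p - w): p]), revcomp(ref[p: p + w])


def junction_flanks(
    junction: Junction, reference: dict[str, str], window: int = DEFAULT_FLANK_WINDOW
) -> tuple[str, str, str, str]:
    """Derivative-oriented (flank_a, flank_b, beyond_a, beyond_b) for a junction.

    Honors the junction's recorded derivative order (coordinate sorting
    may have swapped the endpoints); microhomology is invariant under the
    reading direction, insertion orientation is not.
    """
    if not junction.resolved:
        raise ValueError("cannot extract flanks for an unresolved junction")
    first, second = (
        (junction.bp2, junction.bp1) if junction.swapped else (junction.bp1, junction.bp2)
    )
    fa, beyond_a = _first_endpoint_flanks(reference[first.contig], first, window)
    fb, beyond_b = _second_endpoint_flanks(reference[second.contig], second, window)
    return fa, fb, beyond_a, beyond_b


def classify_junction(
    junction: Junction,
    reference: dict[str, str],
    junction_seq: Optional[str] = None,
    flank_window: int = DEFAULT_FLANK_WINDOW,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    min_templated_len: int = DEFAULT_MIN_TEMPLATED_LEN,
    min_templated_identity: float = DEFAULT_MIN_TEMPLATED_IDENTITY,
) -> JunctionSignature:
    """Full signature of one resolved junction.

    With only the reference, microhomology is computed from the flanks.
    With an observed junction-spanning sequence, inserted bases are
    extracted and classified as well; if the sequence was recorded in the
    opposite orientation its reverse complement is tried before failing.
    """
    fa, fb, beyond_a, beyond_b = junction_flanks(junction, reference, flank_window)
    sig = JunctionSignature(junction_id=junction.id)

    seq = junction_seq if junction_seq is not None else junction.junction_seq
    if seq:
        windows = _search_windows(junction, reference, search_window)
        try:
            call = classify_insertion(
                seq, fa, fb, windows, min_templated_len, min_templated_identity
            )
        except ValueError:
            call = classify_insertion(
                revcomp(seq), fa, fb, windows, min_templated_len, min_templated_identity
            )
        sig.insertion_seq = call.seq or None
        sig.insertion_len = call.length
        sig.insertion_origin = call.origin
        sig.templated_locus = call.locus
        sig.templated_identity = call.identity
        if call.origin == InsertionOrigin.TEMPLATED and call.inverted:
            sig.flags.append("short_inversion")
        if call.length and is_simple_repeat(call.seq):
            sig.flags.append("simple_repeat")

    sig.microhomology_len = microhomology(fa, fb, beyond_a, beyond_b)

    if _flank_similarity(fa, beyond_b):
        sig.flags.append("flank_similarity")
    return sig


def _search_windows(
    junction: Junction, reference: dict[str, str], w: int
) -> list[tuple[str, str]]:
    out = []
    for name, bp in (("near_bp1", junction.bp1), ("near_bp2", junction.bp2)):
        ref = reference[bp.contig]
        lo, hi = max(0, bp.position - w), min(len(ref), bp.position + w)
        out.append((name, ref[lo:hi]))
    return out


def _flank_similarity(
    flank_a: str, ref_beyond_b: str, length: int = 50, min_identity: float = 0.8
) -> bool:
    """Fuzzy similarity of the two reference copies upstream of the join."""
    a, b = flank_a[-length:], ref_beyond_b[-length:]
    if len(a) < length or len(b) < length:
        return False
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / length >= min_identity


# --------------------------------------------------------------------------
# mechanism heuristics
# --------------------------------------------------------------------------

class Mechanism(str, Enum):
    CHROMOANASYNTHESIS = "CHROMOANASYNTHESIS"
    ALU_MEDIATED_RING = "ALU_MEDIATED_RING"
    SIMPLE_NHEJ_LIKE = "SIMPLE_NHEJ_LIKE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class MechanismCall:
    case_id: str
    call: Mechanism
    evidence: list = field(default_factory=list)


def _count_gains(walk: DerivativeWalk) -> int:
    """Number of distinct duplicated reference blocks in the walk."""
    real = [s for s in walk.steps if not s.is_gap]
    if not real:
        return 0
    bounds = sorted({b for s in real for b in (s.interval.start, s.interval.end)})
    dupped = []
    for a, b in zip(bounds, bounds[1:]):
        n = sum(1 for s in real if s.interval.start <= a and b <= s.interval.end)
        dupped.append(n >= 2)
    # merge adjacent duplicated atoms into blocks
    blocks = 0
    prev = False
    for d in dupped:
        if d and not prev:
            blocks += 1
        prev = d
    return blocks


def call_mechanism(
    signatures: Sequence[JunctionSignature],
    walk: DerivativeWalk,
    case_id: str = "",
) -> MechanismCall:
    """Rule-based mechanism call for one case.

    Priority: ring topology (circular walk with terminal losses), then
    replicative chromoanasynthesis (>=3 copy-number gains with >=50% of
    resolved junctions showing 1-100 nt microhomology or a templated
    insert), then a simple end-joining event (<=2 junctions, blunt or
    <=2 nt microhomology).  The ring rule keys on topology only — repeat
    annotation is outside this tool's scope.
    """
    evidence: list[str] = []
    gains = _count_gains(walk)
    n_junctions = walk.junction_count()
    resolved = list(signatures)

    if walk.circular:
        evidence.append("circular derivative (both chromosome ends lost)")
        return MechanismCall(case_id, Mechanism.ALU_MEDIATED_RING, evidence)

    if gains >= 3 and resolved:
        supportive = [
            s
            for s in resolved
            if 1 <= s.microhomology_len <= 100
            or s.insertion_origin == InsertionOrigin.TEMPLATED
        ]
        if len(supportive) >= 0.5 * len(resolved):
            evidence.append(f"{gains} copy-number gains")
            evidence.append(
                f"{len(supportive)}/{len(resolved)} junctions with "
                "microhomology or templated insert"
            )
            return MechanismCall(case_id, Mechanism.CHROMOANASYNTHESIS, evidence)

    if n_junctions <= 2 and all(
        s.blunt or s.microhomology_len <= 2 for s in resolved
    ):
        evidence.append(f"{n_junctions} junction(s), blunt or <=2 nt microhomology")
        return MechanismCall(case_id, Mechanism.SIMPLE_NHEJ_LIKE, evidence)

    evidence.append("no rule fired")
    return MechanismCall(case_id, Mechanism.UNCLASSIFIED, evidence)


__all__ = [
    "DEFAULT_FLANK_WINDOW",
    "DEFAULT_SEARCH_WINDOW",
    "revcomp",
    "microhomology",
    "classify_insertion",
    "classify_junction",
    "junction_flanks",
    "is_simple_repeat",
    "InsertionOrigin",
    "InsertionCall",
    "JunctionSignature",
    "Mechanism",
    "MechanismCall",
    "call_mechanism",
]
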