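"""Shared genomic data model for complex-rearrangement analysis.

Coordinates
-----------
All in-memory coordinates are 0-based half-open.  Segment tables and
nomenclature strings use the 1-based inclusive convention of clinical
reporting; conversion happens at the I/O boundary and is the identity on
round-trip.  A *boundary* is the 0-based position between base ``b-1`` and
base ``b``; breakpoints live on boundaries.

Orientation encoding
--------------------
A junction joins two breakpoint flanks.  Each flank is either the sequence
to the LEFT of the boundary (retained 5' piece, letter ``H``) or to the
RIGHT (letter ``T``).  With breakpoints sorted by coordinate this gives the
four junction classes ``HT`` (reference-like / deletion-type), ``TH``
(tandem-duplication-type) and ``HH``/``TT`` (the two inversion types).
The fixed BEDPE strand mapping is ``HT→(+,+)``, ``HH→(+,−)``,
``TT→(−,+)``, ``TH→(−,−)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence


class Dosage(str, Enum):
    """Dosage class of a segment on the rearranged homolog."""

    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    NML = "NML"
    TELDEL = "TELDEL"  # terminal deletion (telomeric row)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: number of copies of a segment on the *derivative* homolog, by dosage
DERIVATIVE_COPIES = {
    Dosage.DEL: 0,
    Dosage.TELDEL: 0,
    Dosage.NML: 1,
    Dosage.INV: 1,
    Dosage.DUP: 2,
}


class Side(str, Enum):
    """Which flank of a boundary is retained in the derivative."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"


_SIDE_TO_LETTER = {Side.LEFT: "H", Side.RIGHT: "T"}
_LETTER_TO_SIDE = {"H": Side.LEFT, "T": Side.RIGHT}

#: orientation -> (strand1, strand2) for BEDPE emission
ORIENTATION_TO_STRANDS = {
    "HT": ("+", "+"),
    "HH": ("+", "-"),
    "TT": ("-", "+"),
    "TH": ("-", "-"),
}
STRANDS_TO_ORIENTATION = {v: k for k, v in ORIENTATION_TO_STRANDS.items()}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in interval {self}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start},{self.end}) on {self.contig}"
            )

    def length(self) -> int:
        return self.end - self.start

    # -- 1-based inclusive conversion (reporting convention) ---------------
    @classmethod
    def from_1based(cls, contig: str, start1: int, end1: int) -> "GenomicInterval":
        return cls(contig, start1 - 1, end1)

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Segment:
    """A labeled reference interval with a dosage type (one table row)."""

    label: str
    interval: GenomicInterval
    dosage: Dosage
    case_id: str = ""
    method: str = ""

    def length(self) -> int:
        return self.interval.length()


def segment_length(segment: Segment) -> int:
    """Length of a segment in nucleotides (equals table ``end − start + 1``)."""
    return segment.interval.length()


def total_length(
    segments: Iterable[Segment], dosage_filter: Optional[set[Dosage]] = None
) -> int:
    """Summed length of segments whose dosage is in ``dosage_filter``.

    With no filter all segments are summed.  An empty selection returns 0
    with a warning.
    """
    selected = [
        s for s in segments if dosage_filter is None or s.dosage in dosage_filter
    ]
    if not selected:
        warnings.warn("total_length: empty segment selection", stacklevel=2)
        return 0
    return sum(segment_length(s) for s in selected)


def mb(n_nucleotides: int) -> float:
    """Round a nucleotide count to one decimal in megabases (10.3 for 10,339,425)."""
    return round(n_nucleotides / 1e6, 1)


def reference_adjacent(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` abuts ``b`` on the same contig (half-open abutment)."""
    return a.contig == b.contig and a.end == b.start


@dataclass(frozen=True)
class Breakpoint:
    """One endpoint of a novel adjacency, on a 0-based boundary.

    ``resolved=False`` models junctions whose partner could not be mapped
    (the ``?`` entries of derivative nomenclature); such breakpoints carry
    no position claim (``position`` may be None).
    """

    contig: str
    position: Optional[int]
    side: Side
    resolved: bool = True

    def __post_init__(self) -> None:
        if self.resolved:
            if self.position is None or self.position < 0:
                raise ValueError("resolved breakpoint needs a non-negative position")

    @property
    def pos1(self) -> Optional[int]:
        """1-based position of the retained base next to the boundary."""
        if self.position is None:
            return None
        return self.position if self.side == Side.LEFT else self.position + 1


@dataclass
class Junction:
    """An oriented novel adjacency between two breakpoints.

    ``orientation`` is derived from the two sides (H=LEFT, T=RIGHT, first
    letter for ``bp1``).  ``gap_entry`` marks an endpoint that opens an
    unresolved stretch of the derivative (the partner segment has no known
    far end); it is allowed to sit off every copy-number boundary.
    """

    bp1: Breakpoint
    bp2: Breakpoint
    junction_seq: Optional[str] = None
    id: str = ""
    gap_entry: bool = False
    #: True when canonical coordinate sorting reversed the derivative order
    #: of the endpoints (bp2 is then the derivative-first endpoint)
    swapped: bool = False

    def __post_init__(self) -> None:
        if self.junction_seq is not None and not self.junction_seq:
            raise ValueError("junction_seq, when present, must be non-empty")
        # canonical order: sort resolved breakpoints by coordinate
        if (
            self.bp1.resolved
            and self.bp2.resolved
            and (self.bp2.contig, self.bp2.position) < (self.bp1.contig, self.bp1.position)
        ):
            self.bp1, self.bp2 = self.bp2, self.bp1
            self.swapped = not self.swapped

    @property
    def orientation(self) -> str:
        return _SIDE_TO_LETTER[self.bp1.side] + _SIDE_TO_LETTER[self.bp2.side]

    @property
    def resolved(self) -> bool:
        return self.bp1.resolved and self.bp2.resolved

    @classmethod
    def from_orientation(
        cls,
        contig: str,
        pos1: int,
        pos2: int,
        orientation: str,
        **kw,
    ) -> "Junction":
        """Build a junction from two 0-based boundaries and an HT/HH/TT/TH code."""
        if orientation not in ORIENTATION_TO_STRANDS:
            raise ValueError(f"unknown orientation {orientation!r}")
        s1, s2 = (_LETTER_TO_SIDE[c] for c in orientation)
        return cls(Breakpoint(contig, pos1, s1), Breakpoint(contig, pos2, s2), **kw)


@dataclass(frozen=True)
class WalkStep:
    """One step of a derivative walk.

    A regular step is an oriented reference interval.  A *gap* step
    (``interval is None``) stands for sequence whose far end is unresolved;
    ``anchor`` keeps the known 1-based start coordinate when there is one.
    """

    interval: Optional[GenomicInterval]
    inverted: bool = False
    anchor: Optional[int] = None

    @property
    def is_gap(self) -> bool:
        return self.interval is None

    def reverse(self) -> "WalkStep":
        if self.is_gap:
            return self
        return WalkStep(self.interval, not self.inverted, self.anchor)


def derivative_adjacent(a: WalkStep, b: WalkStep) -> bool:
    """True iff step ``b`` continues step ``a`` along the reference."""
    if a.is_gap or b.is_gap:
        return False
    if a.inverted != b.inverted:
        return False
    if not a.inverted:
        return reference_adjacent(a.interval, b.interval)
    return reference_adjacent(b.interval, a.interval)


@dataclass
class DerivativeWalk:
    """An ordered, oriented list of reference intervals; linear or circular.

    Consecutive steps are joined either by a reference adjacency or by a
    novel adjacency; for a circular walk the last→first join counts too.
    ``novel_adjacencies`` optionally carries the Junction objects realizing
    the non-reference joins, in join order.
    """

    steps: list[WalkStep]
    circular: bool = False
    novel_adjacencies: list[Junction] = field(default_factory=list)

    # ------------------------------------------------------------------ joins
    def joins(self) -> list[tuple[int, int]]:
        """Index pairs of consecutive steps (with wrap-around if circular)."""
        n = len(self.steps)
        out = [(i, i + 1) for i in range(n - 1)]
        if self.circular and n > 1:
            out.append((n - 1, 0))
        elif self.circular and n == 1:
            out.append((0, 0))
        return out

    def novel_joins(self) -> list[tuple[int, int]]:
        """Joins that are not reference adjacencies (the junctions)."""
        return [
            (i, j)
            for i, j in self.joins()
            if not derivative_adjacent(self.steps[i], self.steps[j])
        ]

    def junction_count(self) -> int:
        return len(self.novel_joins())

    @property
    def gaps(self) -> list[int]:
        return [i for i, s in enumerate(self.steps) if s.is_gap]

    def length(self) -> int:
        """Total derivative length over resolved steps, in nucleotides."""
        return sum(s.interval.length() for s in self.steps if not s.is_gap)

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check the structural invariants of a walk.

        Every non-reference join must be backed by exactly one novel
        adjacency when junctions are attached, and no junction may be used
        twice.
        """
        if not self.steps:
            raise ValueError("empty walk")
        if self.novel_adjacencies:
            njoins = self.novel_joins()
            if len(self.novel_adjacencies) != len(njoins):
                raise ValueError(
                    f"walk has {len(njoins)} novel joins but "
                    f"{len(self.novel_adjacencies)} junctions attached"
                )
            seen = set()
            for jx in self.novel_adjacencies:
                key = id(jx)
                if key in seen:
                    raise ValueError("novel adjacency used twice in walk")
                seen.add(key)

    # ---------------------------------------------------------- normalization
    def normalized(self) -> "DerivativeWalk":
        """Merge runs of reference-adjacent steps into single steps."""
        merged: list[WalkStep] = []
        for step in self.steps:
            if merged and derivative_adjacent(merged[-1], step):
                prev = merged[-1]
                if not prev.inverted:
                    iv = GenomicInterval(
                        prev.interval.contig, prev.interval.start, step.interval.end
                    )
                else:
                    iv = GenomicInterval(
                        prev.interval.contig, step.interval.start, prev.interval.end
                    )
                merged[-1] = WalkStep(iv, prev.inverted, prev.anchor)
            else:
                merged.append(step)
        # circular wrap: first/last may merge too
        if self.circular and len(merged) > 1 and derivative_adjacent(merged[-1], merged[0]):
            last, first = merged[-1], merged[0]
            if not last.inverted:
                iv = GenomicInterval(
                    last.interval.contig, last.interval.start, first.interval.end
                )
            else:
                iv = GenomicInterval(
                    last.interval.contig, first.interval.start, last.interval.end
                )
            merged = [WalkStep(iv, last.inverted, last.anchor)] + merged[1:-1]
        return DerivativeWalk(merged, circular=self.circular)

    def reversed(self) -> "DerivativeWalk":
        return DerivativeWalk(
            [s.reverse() for s in reversed(self.steps)], circular=self.circular
        )

    # ------------------------------------------------------------- comparison
    def _key(self) -> tuple:
        def stepkey(s: WalkStep):
            if s.is_gap:
                return ("gap", s.anchor if s.anchor is not None else -1, s.inverted)
            return (s.interval.contig, s.interval.start, s.interval.end, s.inverted)

        return tuple(stepkey(s) for s in self.steps)

    def canonical(self) -> "DerivativeWalk":
        """Canonical representative under reflection (and rotation if circular)."""
        w = self.normalized()
        candidates = [w, w.reversed()]
        if w.circular:
            rotated = []
            for cand in candidates:
                n = len(cand.steps)
                for k in range(n):
                    rotated.append(
                        DerivativeWalk(
                            cand.steps[k:] + cand.steps[:k], circular=True
                        )
                    )
            candidates = rotated
        return min(candidates, key=lambda c: c._key())

    def equivalent(self, other: "DerivativeWalk") -> bool:
        """Equality up to normalization, reflection, and (ring) rotation."""
        if self.circular != other.circular:
            return False
        return self.canonical()._key() == other.canonical()._key()


def identity_walk(contig: str, length: int) -> DerivativeWalk:
    """The reference-identical walk over one contig."""
    return DerivativeWalk([WalkStep(GenomicInterval(contig, 0, length))])


def check_no_same_dosage_overlap(segments: Sequence[Segment]) -> None:
    """Raise if two segments of the same dosage class overlap."""
    by_dosage: dict[Dosage, list[Segment]] = {}
    for s in segments:
        by_dosage.setdefault(s.dosage, []).append(s)
    for dosage, segs in by_dosage.items():
        segs = sorted(segs, key=lambda s: (s.interval.contig, s.interval.start))
        for a, b in zip(segs, segs[1:]):
            if a.interval.overlaps(b.interval):
                raise ValueError(
                    f"{dosage} segments {a.label} and {b.label} overlap"
                )


def count_case_breakpoints(
    segments: Sequence[Segment], contig_length: Optional[int] = None
) -> int:
    """Count breakpoints as 2 per DEL/DUP/INV row, deduplicated on boundaries.

    Boundaries shared by abutting rows are counted once.  Chromosome
    termini (position 0 and ``contig_length``) are excluded when only
    deletion-type rows touch them: a lost telomeric end is not a junction
    endpoint, whereas a duplication reaching the terminus still is.
    """
    boundaries: dict[int, set[Dosage]] = {}
    for s in segments:
        if s.dosage not in (Dosage.DEL, Dosage.DUP, Dosage.INV, Dosage.TELDEL):
            continue
        for b in (s.interval.start, s.interval.end):
            boundaries.setdefault(b, set()).add(s.dosage)
    count = 0
    for b, dosages in boundaries.items():
        terminal = b == 0 or (contig_length is not None and b == contig_length)
        if terminal and dosages <= {Dosage.DEL, Dosage.TELDEL}:
            continue
        count += 1
    return count


__all__ = [
    "Dosage",
    "Side",
    "DERIVATIVE_COPIES",
    "ORIENTATION_TO_STRANDS",
    "STRANDS_TO_ORIENTATION",
    "GenomicInterval",
    "Segment",
    "Breakpoint",
    "Junction",
    "WalkStep",
    "DerivativeWalk",
    "segment_length",
    "total_length",
    "mb",
    "reference_adjacent",
    "derivative_adjacent",
    "identity_walk",
    "check_no_same_dosage_overlap",
    "count_case_breakpoints",
]
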