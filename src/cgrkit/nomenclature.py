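"""Parser and emitter for ISCN-like ``g.[...]`` derivative descriptions.

The dialect covers exactly the constructs used in clinical derivative
strings for complex intrachromosomal rearrangements::

    expr      :=  element ((';' | '::') element)*
    element   :=  range
                | range 'inv'
                | range 'del'
                | range 'delins' '[' expr ']'
                | range 'ins' (range ['inv'] | '[' expr ']')
                | pos '_' '?'                  (unresolved partner)
                | '?'
    range     :=  pos '_' pos
    pos       :=  integer | 'pter' | 'qter' | '(' integer '_' integer ')'

Coordinates are 1-based inclusive.  Uncertain positions ``(lo_hi)``
resolve to the interval midpoint for walk construction; the range is kept
on the node.  Lenient mode repairs two recoverable defect classes seen in
printed strings — a stray ``inv:`` separator (read as ``inv;``) and a
surplus digit in an insertion target — recording each in a diagnostics
list instead of failing.

Ring convention: a parsed derivative whose walk retains neither the first
(pter) nor the last (qter) reference base is treated as circular — both
broken ends are taken to be rescued by ring formation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

from .core import DerivativeWalk, GenomicInterval, WalkStep

DEFAULT_CONTIG = "chr21"


class NomenclatureError(ValueError):
    pass


# --------------------------------------------------------------------------
# positions
# --------------------------------------------------------------------------

class _Anchor:
    def __init__(self, name: str):
        self.name = name

    def __repr__(self) -> str:
        return self.name

    def __deepcopy__(self, memo):  # singletons
        return self


PTER = _Anchor("pter")
QTER = _Anchor("qter")


@dataclass(frozen=True)
class UncertainPos:
    lo: int
    hi: int

    @property
    def midpoint(self) -> int:
        return (self.lo + self.hi) // 2


Pos = Union[int, UncertainPos, _Anchor]


def resolve_pos(p: Pos, contig_length: Optional[int] = None) -> int:
    """Resolve a position token to a concrete 1-based coordinate."""
    if isinstance(p, int):
        return p
    if isinstance(p, UncertainPos):
        return p.midpoint
    if p is PTER:
        return 1
    if p is QTER:
        if contig_length is None:
            raise NomenclatureError("qter used but contig length unknown")
        return contig_length
    raise NomenclatureError(f"cannot resolve position {p!r}")


# --------------------------------------------------------------------------
# AST nodes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Range:
    start: Pos
    end: Pos


@dataclass(frozen=True)
class Inv:
    child: Range


@dataclass(frozen=True)
class Unknown:
    """An unresolved element; ``anchor`` is the known start when written ``a_?``."""

    anchor: Optional[Pos] = None


@dataclass(frozen=True)
class Del:
    target: Range


@dataclass(frozen=True)
class DelIns:
    target: Range
    replacement: tuple

    def __post_init__(self):
        if not self.replacement:
            raise NomenclatureError("delins with empty replacement")


@dataclass(frozen=True)
class Ins:
    at: Range  # (p, p+1): insertion between the two flanking bases
    insert: tuple


Node = Union[Range, Inv, Unknown, Del, DelIns, Ins]


@dataclass
class SeqExpr:
    """Parsed ``g.[...]`` expression: top-level nodes plus parse metadata."""

    parts: list
    separators: list = field(default_factory=list)
    accession: str = ""
    diagnostics: list = field(default_factory=list)
    text: str = ""


# --------------------------------------------------------------------------
# parser
# --------------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str, lenient: bool):
        self.t = text
        self.i = 0
        self.lenient = lenient
        self.diagnostics: list[str] = []

    def err(self, msg: str) -> NomenclatureError:
        return NomenclatureError(f"{msg} at character offset {self.i}")

    def eof(self) -> bool:
        return self.i >= len(self.t)

    def startswith(self, s: str) -> bool:
        return self.t.startswith(s, self.i)

    # -- tokens ------------------------------------------------------------
    def number(self) -> int:
        j = self.i
        while j < len(self.t) and self.t[j].isdigit():
            j += 1
        if j == self.i:
            raise self.err("expected a number")
        n = int(self.t[self.i : j])
        self.i = j
        return n

    def pos(self) -> Pos:
        if self.startswith("pter"):
            self.i += 4
            return PTER
        if self.startswith("qter"):
            self.i += 4
            return QTER
        if self.startswith("("):
            self.i += 1
            lo = self.number()
            if not self.startswith("_"):
                raise self.err("expected '_' in uncertain position")
            self.i += 1
            hi = self.number()
            if not self.startswith(")"):
                raise self.err("expected ')' closing uncertain position")
            self.i += 1
            return UncertainPos(lo, hi)
        return self.number()

    # -- separators ---------------------------------------------------------
    def separator(self) -> Optional[str]:
        """Consume and return ';' or '::' if present (with lenient ':' repair)."""
        if self.startswith("::"):
            self.i += 2
            return "::"
        if self.startswith(";"):
            self.i += 1
            return ";"
        if self.startswith(":"):
            if self.lenient:
                self.diagnostics.append(
                    f"stray ':' separator at offset {self.i} read as ';'"
                )
                self.i += 1
                return ";"
            raise self.err("stray ':' separator")
        return None

    # -- elements ------------------------------------------------------------
    def element_list(self, closer: Optional[str]) -> tuple[list, list]:
        parts: list[Node] = []
        seps: list[str] = []
        while True:
            parts.append(self.element())
            if closer is not None and self.startswith(closer):
                self.i += 1
                return parts, seps
            if self.eof():
                if closer is None:
                    return parts, seps
                raise self.err(f"expected {closer!r}")
            sep = self.separator()
            if sep is None:
                raise self.err("expected ';' or '::' between elements")
            seps.append(sep)

    def element(self) -> Node:
        if self.startswith("?"):
            self.i += 1
            return Unknown()
        p1 = self.pos()
        if not self.startswith("_"):
            raise self.err("expected '_' after position")
        self.i += 1
        if self.startswith("?"):
            self.i += 1
            return Unknown(anchor=p1)
        p2 = self.pos()
        rng = Range(p1, p2)
        if self.startswith("delins"):
            self.i += 6
            if not self.startswith("["):
                raise self.err("expected '[' after delins")
            self.i += 1
            parts, _ = self.element_list("]")
            return DelIns(rng, tuple(parts))
        if self.startswith("del"):
            self.i += 3
            return Del(rng)
        if self.startswith("ins"):
            self.i += 3
            rng = self._repair_ins_target(rng)
            if self.startswith("["):
                self.i += 1
                parts, _ = self.element_list("]")
                return Ins(rng, tuple(parts))
            q1 = self.pos()
            if not self.startswith("_"):
                raise self.err("expected '_' in ins range")
            self.i += 1
            q2 = self.pos()
            child: Node = Range(q1, q2)
            if self.startswith("inv"):
                self.i += 3
                child = Inv(child)
            return Ins(rng, (child,))
        if self.startswith("inv"):
            self.i += 3
            return Inv(rng)
        return rng

    def _repair_ins_target(self, rng: Range) -> Range:
        """Insertion targets must name two adjacent bases ``p_(p+1)``.

        A printed target whose second coordinate carries one surplus digit
        (an adjacent base with a trailing typo digit) is repaired in
        lenient mode.
        """
        if not (isinstance(rng.start, int) and isinstance(rng.end, int)):
            return rng
        a, b = rng.start, rng.end
        if b == a + 1:
            return rng
        sa, sb = str(a), str(b)
        if self.lenient and len(sb) == len(sa) + 1 and (
            sb.startswith(sa) or sb[:-1] == str(a + 1)
        ):
            self.diagnostics.append(
                f"insertion target {a}_{b}: surplus digit, read as {a}_{a + 1}"
            )
            return Range(a, a + 1)
        raise self.err(f"insertion target {a}_{b} does not name adjacent bases")


def _extract_g_body(text: str) -> tuple[str, str]:
    """Return (accession, body) for the ``g.[...]`` portion of a string."""
    text = text.strip().replace(",", "").replace(" ", "")
    idx = text.find("g.[")
    if idx < 0:
        raise NomenclatureError("no 'g.[' expression found")
    accession = text[:idx].rstrip(":")
    # the accession may be preceded by karyotype / cytoband prose; keep tail token
    if ":" in accession:
        accession = accession.split(":")[-1]
    body_start = idx + 3
    depth = 1
    for j in range(body_start, len(text)):
        if text[j] == "[":
            depth += 1
        elif text[j] == "]":
            depth -= 1
            if depth == 0:
                return accession, text[body_start:j]
    raise NomenclatureError(
        f"unbalanced brackets at character offset {len(text)}"
    )


def parse_seq(text: str, lenient: bool = True) -> SeqExpr:
    """Parse one derivative description into an AST.

    Accepts a bare ``g.[...]`` expression or a full ``NC_...:g.[...]``
    string; a leading ``seq[...]`` / ``der(...)`` cytoband part is ignored
    for structure.  Unbalanced brackets are a hard error with the character
    offset; in lenient mode recoverable defects are recorded in
    ``SeqExpr.diagnostics``.
    """
    accession, body = _extract_g_body(text)
    p = _Parser(body, lenient)
    parts, seps = p.element_list(None)
    return SeqExpr(
        parts=parts,
        separators=seps,
        accession=accession,
        diagnostics=p.diagnostics,
        text=text,
    )


# --------------------------------------------------------------------------
# expression -> walk
# --------------------------------------------------------------------------

def _replacement_steps(
    nodes: tuple, contig: str, contig_length: int
) -> list[WalkStep]:
    steps: list[WalkStep] = []
    for node in nodes:
        if isinstance(node, Unknown):
            anchor = (
                resolve_pos(node.anchor, contig_length)
                if node.anchor is not None
                else None
            )
            steps.append(WalkStep(None, anchor=anchor))
        elif isinstance(node, Inv):
            s1 = resolve_pos(node.child.start, contig_length)
            e1 = resolve_pos(node.child.end, contig_length)
            steps.append(WalkStep(GenomicInterval.from_1based(contig, s1, e1), True))
        elif isinstance(node, Range):
            s1 = resolve_pos(node.start, contig_length)
            e1 = resolve_pos(node.end, contig_length)
            steps.append(WalkStep(GenomicInterval.from_1based(contig, s1, e1), False))
        else:
            raise NomenclatureError(
                f"nested edit {type(node).__name__} not supported in replacement"
            )
    return steps


def seq_to_walk(
    expr: SeqExpr, contig_length: int, contig: str = DEFAULT_CONTIG
) -> DerivativeWalk:
    """Convert a parsed expression into a derivative walk.

    The walk consists of the non-deleted reference runs plus the
    replacement/insert elements in order; inversion flags come from
    ``inv`` nodes and unresolved elements become gap steps.  Overlapping
    edit targets are an error.
    """
    # collect edits as (target_start0, target_end0, replacement steps)
    edits: list[tuple[int, int, list[WalkStep]]] = []
    for node in expr.parts:
        if isinstance(node, Range):
            # a plain reference statement (identity run); contributes no edit
            continue
        if isinstance(node, DelIns):
            s0 = resolve_pos(node.target.start, contig_length) - 1
            e0 = resolve_pos(node.target.end, contig_length)
            edits.append((s0, e0, _replacement_steps(node.replacement, contig, contig_length)))
        elif isinstance(node, Del):
            s0 = resolve_pos(node.target.start, contig_length) - 1
            e0 = resolve_pos(node.target.end, contig_length)
            edits.append((s0, e0, []))
        elif isinstance(node, Ins):
            p = resolve_pos(node.at.start, contig_length)  # insert after base p
            edits.append((p, p, _replacement_steps(node.insert, contig, contig_length)))
        else:
            raise NomenclatureError(
                f"unsupported top-level element {type(node).__name__}"
            )

    edits.sort(key=lambda e: (e[0], e[1]))
    for (s1, e1, _), (s2, e2, _) in zip(edits, edits[1:]):
        if s2 < e1:
            raise NomenclatureError(
                f"overlapping edit targets [{s1},{e1}) and [{s2},{e2})"
            )

    steps: list[WalkStep] = []
    cursor = 0
    for s0, e0, repl in edits:
        if s0 > cursor:
            steps.append(WalkStep(GenomicInterval(contig, cursor, s0)))
        steps.extend(repl)
        cursor = max(cursor, e0)
    if cursor < contig_length:
        steps.append(WalkStep(GenomicInterval(contig, cursor, contig_length)))
    if not steps:
        raise NomenclatureError("expression describes an empty derivative")

    circular = _is_ring(steps, contig_length)
    return DerivativeWalk(steps, circular=circular)


def _is_ring(steps: list[WalkStep], contig_length: int) -> bool:
    """Ring convention: neither terminal reference base is retained."""
    has_pter = any(
        not s.is_gap and s.interval.contains(0) for s in steps
    )
    has_qter = any(
        not s.is_gap and s.interval.contains(contig_length - 1) for s in steps
    )
    return not has_pter and not has_qter


# --------------------------------------------------------------------------
# walk -> expression text
# --------------------------------------------------------------------------

def _fmt_step(step: WalkStep) -> str:
    if step.is_gap:
        return f"{step.anchor}_?" if step.anchor is not None else "?"
    s1, e1 = step.interval.to_1based()
    return f"{s1}_{e1}" + ("inv" if step.inverted else "")


def walk_to_seq(walk: DerivativeWalk, contig_length: int, accession: str = "") -> str:
    """Emit a canonical derivative description for a walk.

    The inverse of :func:`parse_seq` + :func:`seq_to_walk` on normalized
    walks: ``seq_to_walk(parse_seq(walk_to_seq(w))) == w.normalized()``.
    Gap steps are written as ``?`` tokens.
    """
    w = walk.normalized()
    prefix = f"{accession}:g.[" if accession else "g.["

    if w.circular:
        inner = ";".join(_fmt_step(s) for s in w.steps)
        return f"{prefix}pter_qterdelins[{inner}]]"

    steps = list(w.steps)
    head: Optional[WalkStep] = None
    tail: Optional[WalkStep] = None
    if steps and not steps[0].is_gap and not steps[0].inverted and steps[0].interval.start == 0:
        head = steps.pop(0)
    if steps and not steps[-1].is_gap and not steps[-1].inverted and steps[-1].interval.end == contig_length:
        tail = steps.pop()

    if head is not None and tail is None and not steps and head.interval.end == contig_length:
        return f"{prefix}pter_qter]"

    if head is not None and tail is not None and tail.interval.start < head.interval.end:
        # duplicated run spanning the join: describe as an insertion of the
        # re-copied piece right after the head flank
        if not steps:
            p = head.interval.end  # 1-based last head base
            ins = f"{tail.interval.start + 1}_{head.interval.end}"
            return f"{prefix}{p}_{p + 1}ins{ins}]"
        steps.append(tail)  # keep the tail as an explicit element
        tail = None

    if head is None and tail is None and not any(
        not s.is_gap and (s.interval.contains(0) or s.interval.contains(contig_length - 1))
        for s in steps
    ):
        warnings.warn(
            "linear walk retains neither chromosome end; its description "
            "will re-parse as a ring",
            stacklevel=2,
        )

    ts = "pter" if head is None else str(head.interval.end + 1)
    te = "qter" if tail is None else str(tail.interval.start)

    if not steps:
        return f"{prefix}{ts}_{te}del]"

    # pure insertion: flanks abut
    if (
        head is not None
        and tail is not None
        and head.interval.end == tail.interval.start
    ):
        p = head.interval.end  # 1-based coordinate of last head base
        if len(steps) == 1 and not steps[0].is_gap:
            return f"{prefix}{p}_{p + 1}ins{_fmt_step(steps[0])}]"
        inner = ";".join(_fmt_step(s) for s in steps)
        return f"{prefix}{p}_{p + 1}ins[{inner}]]"

    inner = ";".join(_fmt_step(s) for s in steps)
    return f"{prefix}{ts}_{te}delins[{inner}]]"


__all__ = [
    "PTER",
    "QTER",
    "UncertainPos",
    "Range",
    "Inv",
    "Unknown",
    "Del",
    "DelIns",
    "Ins",
    "SeqExpr",
    "NomenclatureError",
    "parse_seq",
    "seq_to_walk",
    "walk_to_seq",
    "resolve_pos",
    "DEFAULT_CONTIG",
]
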