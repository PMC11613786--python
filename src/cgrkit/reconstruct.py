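"""Breakpoint-graph construction and derivative-walk assembly.

The manual procedure of following junction-spanning (soft-clipped) read
evidence from breakpoint to breakpoint is formalized as a graph search:

* the reference region is partitioned into *atoms* at every copy-number
  segment boundary;
* each atom carries the number of copies it contributes to the derivative
  homolog (0 for a deletion, 1 for retained/inverted, 2 for a single-gain
  duplication, or ``cn − 1`` from an explicit total copy number);
* each junction is a *novel edge* joining two breakpoint flanks, with
  multiplicity one.

A consistent derivative is a walk that traverses every atom exactly its
copy count and uses every novel edge exactly once, ending at a telomeric
end (linear) or closing on itself (ring).  The search is exhaustive with
deterministic tie-breaking (novel edges before reference continuation,
lower coordinate first) and a configurable state budget; all consistent
walks are returned and more than one flags the evidence as ambiguous.

Junctions with an unresolved partner terminate a branch into an explicit
gap step; traversal resumes through the paired half-junction and the gap
is reported on the walk.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .core import (
    DERIVATIVE_COPIES,
    Breakpoint,
    DerivativeWalk,
    Dosage,
    GenomicInterval,
    Junction,
    Segment,
    Side,
    WalkStep,
    derivative_adjacent,
)

_GAP = ("gap",)


class ReconstructionError(ValueError):
    pass


class InconsistentEvidenceError(ReconstructionError):
    """No derivative walk satisfies the copy-number and junction constraints."""


# --------------------------------------------------------------------------
# graph model
# --------------------------------------------------------------------------

@dataclass
class BreakpointGraph:
    contig: str
    atoms: list[GenomicInterval]  # sorted partition of the region
    copies: list[int]  # derivative copies per atom
    junctions: list[Junction]
    # per junction, the two endpoint descriptors:
    #   ("boundary", pos, side) | ("gap_anchor", pos, side) | ("unresolved",)
    endpoints: list[tuple] = field(default_factory=list)

    @property
    def boundaries(self) -> list[int]:
        return [a.start for a in self.atoms] + [self.atoms[-1].end]


def _endpoint_descriptor(
    bp: Breakpoint, boundary_set: set[int], boundaries: list[int],
    tolerance: int, gap_entry: bool,
):
    if not bp.resolved or bp.position is None:
        return ("unresolved",), bp
    pos = bp.position
    if pos in boundary_set:
        return ("boundary", pos, bp.side), bp
    # snap within tolerance
    i = bisect_left(boundaries, pos)
    near = [boundaries[j] for j in (i - 1, i) if 0 <= j < len(boundaries)]
    best = min(near, key=lambda b: abs(b - pos)) if near else None
    if best is not None and tolerance > 0 and abs(best - pos) <= tolerance:
        return ("boundary", best, bp.side), Breakpoint(bp.contig, best, bp.side)
    if gap_entry:
        return ("gap_anchor", pos, bp.side), bp
    raise ReconstructionError(
        f"junction endpoint at {pos} matches no segment boundary "
        f"(nearest: {near}, tolerance {tolerance})"
    )


def build_graph(
    segments: Sequence[Segment],
    junctions: Sequence[Junction],
    cn_per_segment: Optional[dict] = None,
    tolerance: int = 0,
    region: Optional[GenomicInterval] = None,
) -> BreakpointGraph:
    """Build the breakpoint graph from copy-number segments and junctions.

    Gaps between segments are auto-filled as copy-neutral atoms.
    ``cn_per_segment`` optionally maps segment labels to *total* copy
    numbers (derivative copies are ``cn − 1``); otherwise copies derive
    from each segment's dosage class.  Junction endpoints must coincide
    with segment boundaries within ``tolerance`` (default 0) unless they
    open an unresolved gap.
    """
    if not segments:
        raise ReconstructionError("no segments")
    contig = segments[0].interval.contig
    segs = sorted(segments, key=lambda s: s.interval.start)
    lo = region.start if region else 0
    hi = region.end if region else None

    bset = {lo}
    for s in segs:
        bset.update((s.interval.start, s.interval.end))
    if hi is not None:
        bset.add(hi)
    bounds = sorted(b for b in bset if (hi is None or b <= hi) and b >= lo)

    atoms, copies = [], []
    for a, b in zip(bounds, bounds[1:]):
        iv = GenomicInterval(contig, a, b)
        cover = [s for s in segs if s.interval.start <= a and b <= s.interval.end]
        if not cover:
            c = 1  # auto-filled copy-neutral atom
        else:
            cs = set()
            for s in cover:
                if cn_per_segment and s.label in cn_per_segment:
                    cs.add(max(0, int(cn_per_segment[s.label]) - 1))
                else:
                    cs.add(DERIVATIVE_COPIES[s.dosage])
            if len(cs) > 1:
                raise ReconstructionError(
                    f"conflicting copy numbers {sorted(cs)} over [{a},{b})"
                )
            c = cs.pop()
        atoms.append(iv)
        copies.append(c)

    graph = BreakpointGraph(contig, atoms, copies, [], [])
    boundary_set = set(graph.boundaries)
    blist = graph.boundaries
    for jx in junctions:
        d1, bp1 = _endpoint_descriptor(jx.bp1, boundary_set, blist, tolerance, jx.gap_entry)
        d2, bp2 = _endpoint_descriptor(jx.bp2, boundary_set, blist, tolerance, jx.gap_entry)
        graph.junctions.append(
            Junction(bp1, bp2, junction_seq=jx.junction_seq, id=jx.id, gap_entry=jx.gap_entry)
        )
        graph.endpoints.append((d1, d2))
    return graph


# --------------------------------------------------------------------------
# truth extraction from a walk (the inverse problem)
# --------------------------------------------------------------------------

def junctions_from_walk(walk: DerivativeWalk, id_prefix: str = "J") -> list[Junction]:
    """The novel adjacencies a walk implies, one Junction per novel join."""

    def exit_endpoint(step: WalkStep) -> Breakpoint:
        if step.is_gap:
            return Breakpoint(".", None, Side.LEFT, resolved=False)
        if step.inverted:
            return Breakpoint(step.interval.contig, step.interval.start, Side.RIGHT)
        return Breakpoint(step.interval.contig, step.interval.end, Side.LEFT)

    def entry_endpoint(step: WalkStep) -> tuple[Breakpoint, bool]:
        if step.is_gap:
            if step.anchor is not None:
                # known 1-based start of sequence running into the unknown
                return (
                    Breakpoint(walk.steps[0].interval.contig if not walk.steps[0].is_gap else ".",
                               step.anchor - 1, Side.RIGHT),
                    True,
                )
            return Breakpoint(".", None, Side.LEFT, resolved=False), False
        if step.inverted:
            return Breakpoint(step.interval.contig, step.interval.end, Side.LEFT), False
        return Breakpoint(step.interval.contig, step.interval.start, Side.RIGHT), False

    out = []
    for k, (i, j) in enumerate(walk.novel_joins(), start=1):
        bp_a = exit_endpoint(walk.steps[i])
        bp_b, gap_entry = entry_endpoint(walk.steps[j])
        out.append(Junction(bp_a, bp_b, id=f"{id_prefix}{k}", gap_entry=gap_entry))
    return out


def graph_from_walk(walk: DerivativeWalk, contig_length: int) -> BreakpointGraph:
    """Partition + copy numbers + junctions implied by a truth walk."""
    real = [s for s in walk.steps if not s.is_gap]
    if not real:
        raise ReconstructionError("walk has no resolved steps")
    contig = real[0].interval.contig
    bset = {0, contig_length}
    for s in real:
        bset.update((s.interval.start, s.interval.end))
    bounds = sorted(bset)
    atoms, copies = [], []
    for a, b in zip(bounds, bounds[1:]):
        atoms.append(GenomicInterval(contig, a, b))
        copies.append(
            sum(1 for s in real if s.interval.start <= a and b <= s.interval.end)
        )
    graph = BreakpointGraph(contig, atoms, copies, [], [])
    boundary_set = set(graph.boundaries)
    blist = graph.boundaries
    for jx in junctions_from_walk(walk):
        d1, bp1 = _endpoint_descriptor(jx.bp1, boundary_set, blist, 0, jx.gap_entry)
        d2, bp2 = _endpoint_descriptor(jx.bp2, boundary_set, blist, 0, jx.gap_entry)
        graph.junctions.append(Junction(bp1, bp2, id=jx.id, gap_entry=jx.gap_entry))
        graph.endpoints.append((d1, d2))
    return graph


def segments_from_graph(graph: BreakpointGraph, case_id: str = "") -> list[Segment]:
    """Atoms as labeled dosage segments (DEL/NML/DUP by copy count)."""
    out = []
    for i, (iv, c) in enumerate(zip(graph.atoms, graph.copies)):
        dosage = Dosage.DEL if c == 0 else (Dosage.NML if c == 1 else Dosage.DUP)
        out.append(Segment(label=f"S{i + 1}", interval=iv, dosage=dosage, case_id=case_id))
    return out


# --------------------------------------------------------------------------
# walk assembly (exhaustive search)
# --------------------------------------------------------------------------

def assemble_walk(
    graph: BreakpointGraph,
    start: Union[str, int] = "pter",
    max_states: int = 500_000,
) -> list[DerivativeWalk]:
    """Enumerate all derivative walks consistent with the graph.

    Returns every walk (deterministic order, deduplicated up to
    reflection and ring rotation) that consumes each atom copy and each
    novel edge exactly once.  ``start`` may be a 0-based position to
    restrict the first traversed atom.  Raises
    :class:`InconsistentEvidenceError` when no walk exists and
    :class:`ReconstructionError` when the state budget is exceeded.
    """
    n_atoms = len(graph.atoms)
    n_edges = len(graph.junctions)
    full_mask = (1 << n_edges) - 1

    left_at = {a.start: i for i, a in enumerate(graph.atoms)}
    right_at = {a.end: i for i, a in enumerate(graph.atoms)}
    edges_at: dict[tuple, list[int]] = {}
    gap_edges: list[int] = []
    for ei, (d1, d2) in enumerate(graph.endpoints):
        for d in (d1, d2):
            if d[0] == "boundary":
                edges_at.setdefault((d[1], d[2]), []).append(ei)
            elif d[0] == "unresolved":
                gap_edges.append(ei)

    def other_end(ei: int, here: tuple) -> tuple:
        d1, d2 = graph.endpoints[ei]
        return d2 if d1 == here else d1

    results: list[DerivativeWalk] = []
    seen_keys: set = set()
    state_count = 0

    def to_walk(steps: list, junctions_used: list[int], circular: bool) -> DerivativeWalk:
        wsteps = []
        for item in steps:
            if item[0] == "gap":
                wsteps.append(WalkStep(None, anchor=item[1]))
            else:
                wsteps.append(WalkStep(graph.atoms[item[0]], item[1]))
        return DerivativeWalk(
            wsteps,
            circular=circular,
            novel_adjacencies=[graph.junctions[i] for i in junctions_used],
        )

    def record(steps, junctions_used, circular):
        walk = to_walk(steps, junctions_used, circular)
        key = walk.canonical()._key() + (circular,)
        if key not in seen_keys:
            seen_keys.add(key)
            results.append(_prefer_orientation(walk))

    def entry_flank(first) -> Optional[tuple]:
        if first[0] == "gap":
            return None
        atom = graph.atoms[first[0]]
        return (atom.end, Side.LEFT) if first[1] else (atom.start, Side.RIGHT)

    def land(desc: tuple, copies: list, steps: list) -> Optional[tuple]:
        """Traverse the atom a novel edge lands on; returns new flank or None."""
        kind = desc[0]
        if kind != "boundary":
            return None
        _, pos, side = desc
        if side == Side.RIGHT:
            ai = left_at.get(pos)
            if ai is None or copies[ai] == 0:
                return None
            copies[ai] -= 1
            steps.append((ai, False))
            return (graph.atoms[ai].end, Side.LEFT)
        ai = right_at.get(pos)
        if ai is None or copies[ai] == 0:
            return None
        copies[ai] -= 1
        steps.append((ai, True))
        return (graph.atoms[ai].start, Side.RIGHT)

    def dfs(flank, copies, used, steps, junctions_used):
        nonlocal state_count
        state_count += 1
        if state_count > max_states:
            raise ReconstructionError(
                f"walk search exceeded the state budget ({max_states})"
            )
        all_consumed = all(c == 0 for c in copies)
        if flank != _GAP and all_consumed:
            first = steps[0]
            if used == full_mask:
                record(steps, junctions_used, circular=False)
                # reference-adjacency ring closure
                w = to_walk(steps, junctions_used, True)
                if len(w.steps) > 1 and derivative_adjacent(w.steps[-1], w.steps[0]):
                    record(steps, junctions_used, circular=True)
            else:
                remaining = [e for e in range(n_edges) if not used >> e & 1]
                if len(remaining) == 1:
                    d1, d2 = graph.endpoints[remaining[0]]
                    ent = entry_flank(first)
                    if ent is not None and d1[0] == d2[0] == "boundary":
                        pair = {(d1[1], d1[2]), (d2[1], d2[2])}
                        if pair == {flank, ent} or (
                            flank == ent and pair == {flank}
                        ):
                            record(
                                steps,
                                junctions_used + [remaining[0]],
                                circular=True,
                            )

        if flank == _GAP:
            for ei in gap_edges:
                if used >> ei & 1:
                    continue
                d1, d2 = graph.endpoints[ei]
                desc = d2 if d1[0] == "unresolved" else d1
                new_copies = list(copies)
                new_steps = list(steps)
                nf = land(desc, new_copies, new_steps)
                if nf is None:
                    continue
                dfs(nf, new_copies, used | 1 << ei, new_steps, junctions_used + [ei])
            return

        # novel edges first (deterministic by edge index == coordinate order)
        for ei in edges_at.get(flank, []):
            if used >> ei & 1:
                continue
            desc = other_end(ei, ("boundary", flank[0], flank[1]))
            if desc[0] == "boundary":
                new_copies = list(copies)
                new_steps = list(steps)
                nf = land(desc, new_copies, new_steps)
                if nf is None:
                    continue
                dfs(nf, new_copies, used | 1 << ei, new_steps, junctions_used + [ei])
            else:
                anchor = None
                if desc[0] == "gap_anchor":
                    _, pos, side = desc
                    anchor = pos + 1 if side == Side.RIGHT else pos
                new_steps = steps + [("gap", anchor)]
                dfs(_GAP, copies, used | 1 << ei, new_steps, junctions_used + [ei])

        # reference continuation
        pos, side = flank
        if side == Side.LEFT:
            ai = left_at.get(pos)
            if ai is not None and copies[ai] > 0:
                new_copies = list(copies)
                new_copies[ai] -= 1
                dfs(
                    (graph.atoms[ai].end, Side.LEFT),
                    new_copies,
                    used,
                    steps + [(ai, False)],
                    junctions_used,
                )
        else:
            ai = right_at.get(pos)
            if ai is not None and copies[ai] > 0:
                new_copies = list(copies)
                new_copies[ai] -= 1
                dfs(
                    (graph.atoms[ai].start, Side.RIGHT),
                    new_copies,
                    used,
                    steps + [(ai, True)],
                    junctions_used,
                )

    # enumerate start atoms/orientations
    if isinstance(start, int):
        start_atoms = [i for i, a in enumerate(graph.atoms) if a.contains(start)]
    else:
        start_atoms = [i for i in range(n_atoms) if graph.copies[i] > 0]
    for ai in start_atoms:
        if graph.copies[ai] == 0:
            continue
        for inverted in (False, True):
            copies = list(graph.copies)
            copies[ai] -= 1
            flank = (
                (graph.atoms[ai].start, Side.RIGHT)
                if inverted
                else (graph.atoms[ai].end, Side.LEFT)
            )
            dfs(flank, copies, 0, [(ai, inverted)], [])

    if not results:
        raise InconsistentEvidenceError(_diagnose(graph))
    return results


def _prefer_orientation(walk: DerivativeWalk) -> DerivativeWalk:
    """Stable presentation: prefer the reading that ends forward at the
    highest coordinate (the qter-anchored reading for linear walks)."""
    if walk.circular:
        return walk.canonical()
    rev = walk.reversed()

    def score(w: DerivativeWalk):
        last = w.steps[-1]
        first = w.steps[0]
        return (
            0 if (not last.is_gap and not last.inverted) else 1,
            -(last.interval.end if not last.is_gap else -1),
            0 if (not first.is_gap and not first.inverted) else 1,
            w._key(),
        )

    return min((walk, rev), key=score)


def _diagnose(graph: BreakpointGraph) -> str:
    gains = sum(max(0, c - 1) for c in graph.copies)
    losses = sum(1 for c in graph.copies if c == 0)
    return (
        "no derivative walk satisfies the evidence: "
        f"{len(graph.junctions)} novel edges, {gains} atom gains, "
        f"{losses} atom losses could not be jointly traversed"
    )


# --------------------------------------------------------------------------
# summary statistics
# --------------------------------------------------------------------------

def count_breakpoints(
    segments: Sequence[Segment], contig_length: Optional[int] = None
) -> int:
    """Breakpoint count at 2 per SV row, boundary-deduplicated (see core)."""
    from .core import count_case_breakpoints

    return count_case_breakpoints(segments, contig_length)


def count_template_switches(walk: DerivativeWalk) -> int:
    """Novel adjacencies in the walk — a lower bound on template switches
    under a replicative (serial template-switching) model."""
    return walk.junction_count()


def detect_ring(
    walk: DerivativeWalk, segments: Optional[Sequence[Segment]] = None
) -> tuple[bool, dict]:
    """Ring flag plus a summary of segments lost from the derivative."""
    lost = []
    if segments:
        covered = [s.interval for s in walk.steps if not s.is_gap]
        for seg in segments:
            if not any(
                iv.start <= seg.interval.start and seg.interval.end <= iv.end
                for iv in covered
            ):
                lost.append(seg.label)
    return walk.circular, {"circular": walk.circular, "lost_segments": lost}


__all__ = [
    "BreakpointGraph",
    "ReconstructionError",
    "InconsistentEvidenceError",
    "build_graph",
    "graph_from_walk",
    "junctions_from_walk",
    "segments_from_graph",
    "assemble_walk",
    "count_breakpoints",
    "count_template_switches",
    "detect_ring",
]
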