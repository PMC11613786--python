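"""Per-case orchestration: run available stages, emit a JSON report and a
circular derivative plot.

``run_case`` executes whichever stages have inputs — segment summaries
always; walk reconstruction when junctions or a nomenclature string are
present; junction signatures when a reference is supplied; phasing with
trio VCFs; copy number with a depth table — and records which stages
ran.  The report is deterministic: stable key order, no timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import DerivativeWalk, Dosage, Segment, mb, total_length
from .io import CaseBundle, read_phased_snvs, walk_to_dict
from .nomenclature import parse_seq, seq_to_walk, walk_to_seq
from .phasing import run_phasing
from .reconstruct import (
    assemble_walk,
    build_graph,
    count_breakpoints,
    count_template_switches,
    detect_ring,
    junctions_from_walk,
)
from .signature import JunctionSignature, call_mechanism, classify_junction

SCHEMA_VERSION = 1


def _segment_summary(segments: Sequence[Segment], contig_length=None) -> dict:
    per_dosage = {}
    for dosage in Dosage:
        segs = [s for s in segments if s.dosage == dosage]
        if not segs:
            continue
        nt = sum(s.length() for s in segs)
        per_dosage[dosage.value] = {
            "count": len(segs),
            "total_nt": nt,
            "total_mb": mb(nt),
            "labels": [s.label for s in segs],
        }
    return {
        "n_segments": len(segments),
        "per_dosage": per_dosage,
        "breakpoints": count_breakpoints(segments, contig_length),
    }


def _walk_report(walk: DerivativeWalk, segments, contig_length, ambiguous: int) -> dict:
    ring, ring_summary = detect_ring(walk, segments)
    rep = {
        "junction_count": walk.junction_count(),
        "template_switches": count_template_switches(walk),
        "ring": ring,
        "lost_segments": ring_summary["lost_segments"],
        "gaps": walk.gaps,
        "n_steps": len(walk.steps),
        "ambiguous_solutions": ambiguous,
        "walk": walk_to_dict(walk, contig_length),
    }
    if contig_length:
        rep["nomenclature"] = walk_to_seq(walk, contig_length)
    return rep


def run_case(
    bundle: CaseBundle,
    reference: Optional[dict] = None,
    trio_paths: Optional[dict] = None,
    depth_profile=None,
    contig_length: Optional[int] = None,
    tolerance: int = 0,
    use_allelic_depth: bool = True,
) -> dict:
    """Execute all stages for which inputs are available."""
    if not bundle.segments and not bundle.junctions and not bundle.karyotype_string:
        raise ValueError(f"empty bundle for case {bundle.case_id!r}")
    if contig_length is None:
        contig_length = bundle.metadata.get("contig_length")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "case_id": bundle.case_id,
        "stages_run": [],
        "diagnostics": [],
    }

    if bundle.segments:
        report["segments"] = _segment_summary(bundle.segments, contig_length)
        report["stages_run"].append("segments")

    walk: Optional[DerivativeWalk] = None
    ambiguous = 0
    if bundle.junctions and bundle.segments:
        graph = build_graph(bundle.segments, bundle.junctions, tolerance=tolerance)
        walks = assemble_walk(graph)
        walk, ambiguous = walks[0], len(walks)
        report["stages_run"].append("reconstruct")
    elif bundle.karyotype_string and contig_length:
        expr = parse_seq(bundle.karyotype_string)
        report["diagnostics"].extend(expr.diagnostics)
        walk = seq_to_walk(expr, contig_length)
        report["stages_run"].append("nomenclature")
    if walk is not None:
        report["derivative"] = _walk_report(
            walk, bundle.segments, contig_length, ambiguous
        )

    signatures: list[JunctionSignature] = []
    if walk is not None and reference is not None:
        junctions = bundle.junctions or junctions_from_walk(walk)
        for jx in junctions:
            if not jx.resolved or jx.gap_entry:
                continue
            try:
                signatures.append(classify_junction(jx, reference))
            except (KeyError, ValueError) as exc:
                report["diagnostics"].append(f"signature {jx.id}: {exc}")
        mhs = [s.microhomology_len for s in signatures if s.microhomology_len > 0]
        report["signatures"] = {
            "n_classified": len(signatures),
            "n_microhomology": sum(1 for s in signatures if s.microhomology_len > 0),
            "microhomology_range": [min(mhs), max(mhs)] if mhs else None,
            "n_blunt": sum(1 for s in signatures if s.blunt),
            "n_insertions": sum(1 for s in signatures if s.insertion_len > 0),
            "per_junction": [s.to_dict() for s in signatures],
        }
        report["stages_run"].append("signature")
        mech = call_mechanism(signatures, walk, bundle.case_id)
        report["mechanism"] = {"call": mech.call.value, "evidence": mech.evidence}

    if trio_paths is not None and bundle.segments:
        sites = read_phased_snvs(
            trio_paths["child"], trio_paths["father"], trio_paths["mother"]
        )
        phasing = run_phasing(
            sites,
            bundle.segments,
            case_id=bundle.case_id,
            use_allelic_depth=use_allelic_depth,
        )
        report["phasing"] = phasing.to_dict()
        report["stages_run"].append("phasing")

    if depth_profile is not None:
        from .cn import call_cn

        cn_segments = call_cn(depth_profile)
        report["copy_number"] = [
            {"contig": iv.contig, "start": iv.start, "end": iv.end, "cn": cn}
            for iv, cn in cn_segments
        ]
        report["stages_run"].append("copy_number")

    return report


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# plotting
# --------------------------------------------------------------------------

_DOSAGE_COLORS = {0: "#c0392b", 1: "#bdbdbd", 2: "#27ae60"}  # del / neutral / gain


def plot_derivative(
    walk: DerivativeWalk,
    out_path,
    contig_length: Optional[int] = None,
    title: str = "",
) -> None:
    """Circular ideogram of the derivative: the reference as a ring with
    copy-gain (green) and loss (red) shading, inverted steps in blue, and
    one chord per novel adjacency."""
    real = [s for s in walk.steps if not s.is_gap]
    if contig_length is None:
        contig_length = max(s.interval.end for s in real) if real else 1
    L = contig_length

    def theta(pos: float) -> float:
        return np.pi / 2 - 2 * np.pi * pos / L  # clockwise from 12 o'clock

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)

    # coverage per atom -> ring coloring
    bounds = sorted({0, L} | {b for s in real for b in (s.interval.start, s.interval.end)})
    for a, b in zip(bounds, bounds[1:]):
        n = sum(1 for s in real if s.interval.start <= a and b <= s.interval.end)
        color = _DOSAGE_COLORS[min(n, 2)]
        angles = np.linspace(theta(a), theta(b), max(4, int(60 * (b - a) / L)))
        for r in (0.95, 1.0):
            ax.plot(np.cos(angles) * r, np.sin(angles) * r, color=color, lw=3)

    # inverted steps marked on an inner ring
    for s in real:
        if s.inverted:
            angles = np.linspace(
                theta(s.interval.start), theta(s.interval.end), 30
            )
            ax.plot(np.cos(angles) * 0.88, np.sin(angles) * 0.88, color="#2980b9", lw=3)

    # one chord per novel adjacency
    for jx in junctions_from_walk(walk):
        pts = []
        for bp in (jx.bp1, jx.bp2):
            if bp.resolved and bp.position is not None:
                t = theta(bp.position)
                pts.append((np.cos(t) * 0.85, np.sin(t) * 0.85))
        if len(pts) == 2:
            (x1, y1), (x2, y2) = pts
            ax.plot(
                [x1, 0.15 * (x1 + x2), x2],
                [y1, 0.15 * (y1 + y2), y2],
                color="#34495e",
                lw=0.8,
                alpha=0.8,
            )
        elif len(pts) == 1:
            (x1, y1) = pts[0]
            ax.plot([x1, x1 * 0.5], [y1, y1 * 0.5], color="#7f8c8d", lw=0.8, ls=":")
            ax.plot([x1 * 0.5], [y1 * 0.5], marker="o", mfc="none", mec="#7f8c8d")

    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    fig.savefig(str(out_path), dpi=120, bbox_inches="tight")
    plt.close(fig)


__all__ = ["SCHEMA_VERSION", "run_case", "write_report", "plot_derivative"]
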