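"""Synthetic data with known truth: references, derivatives, trios, depth.

Everything the pipeline consumes can be generated here with full truth
tracking, deterministic in the seed:

* random toy references (optionally with planted repeat pairs);
* derivative chromosomes spliced from a truth walk, with junction
  microhomology *planted into the reference flanks* (both copies really
  share the bases, so a brute-force breakpoint-placement oracle agrees)
  and with templated or nontemplated junction insertions;
* trio SNV genotypes consistent with a chosen parental origin — deleted
  segments transmit only the unaffected homolog's allele, duplicated
  segments over-represent the carrier parent at allele dosage 2/3;
* binned read-depth profiles with Poisson noise.

Three named scenarios mirror the statistical structure of the packaged
chromosome-21 case studies at toy scale: ``chromoanasynthesis_dup6``
(six gains, a three-segment inverted cassette, microhomology 1-79 nt and
one 4 nt nontemplated insert), ``ring21`` (two terminal deletions, a
relocated inverted segment, a circular derivative, one blunt junction,
one 40 nt templated insert) and ``mixed_delsdups13`` (deletions plus
inverted duplications, microhomology 1-7 nt, nontemplated 6 nt and
inverted-templated 30 nt inserts, and one unresolved junction partner).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DerivativeWalk,
    GenomicInterval,
    Junction,
    Segment,
    Side,
    WalkStep,
)
from .io import (
    write_depth_tsv,
    write_fasta,
    write_junctions_bedpe,
    write_segment_table,
    write_vcf_bnd,
)
from .reconstruct import graph_from_walk, junctions_from_walk, segments_from_graph
from .signature import microhomology, revcomp

MIN_REFERENCE_LENGTH = 10_000
GAP_FILL = 500  # nt of N emitted for an unresolved walk step
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# --------------------------------------------------------------------------
# reference
# --------------------------------------------------------------------------

def make_reference(
    length: int,
    seed: int,
    repeats: Sequence[tuple[int, int, int]] = (),
) -> str:
    """Uniform-random ACGT sequence, reproducible by seed.

    ``repeats`` plants direct repeat pairs as ``(src_start, dest_start,
    length)`` copies, for templated-insert and homology experiments.
    """
    if length < MIN_REFERENCE_LENGTH:
        raise ValueError(
            f"reference length {length} < minimum {MIN_REFERENCE_LENGTH}"
        )
    rng = np.random.default_rng(seed)
    arr = rng.choice(_BASES, size=length)
    seq = bytearray(arr.tobytes())
    for src, dest, rep_len in repeats:
        seq[dest : dest + rep_len] = seq[src : src + rep_len]
    return seq.decode()


# --------------------------------------------------------------------------
# junction plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertPlan:
    length: int
    origin: str = "nontemplated"  # or "templated"
    offset: int = 300  # distance upstream of breakpoint 1 for templated copies
    inverted: bool = False


@dataclass(frozen=True)
class JunctionPlan:
    microhomology: int = 0
    insertion: Optional[InsertPlan] = None


@dataclass
class SimulatedDerivative:
    """A spliced derivative with complete truth."""

    contig: str
    reference: str
    derivative: str
    walk: DerivativeWalk
    junctions: list[Junction]
    junction_plans: list[Optional[JunctionPlan]]
    junction_seqs: dict[str, str]
    segments: list[Segment]
    cn_total: list[tuple[GenomicInterval, int]]  # total CN incl. normal homolog

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "reference.fa",
            "derivative": out / "derivative.fa",
            "junctions_bedpe": out / "truth_junctions.bedpe",
            "junctions_vcf": out / "truth_junctions.vcf",
            "segments": out / "truth_segments.tsv",
            "junction_seqs": out / "junction_seqs.fa",
            "truth": out / "truth.json",
        }
        write_fasta(paths["reference"], {self.contig: self.reference})
        write_fasta(paths["derivative"], {f"{self.contig}_der": self.derivative})
        write_junctions_bedpe(paths["junctions_bedpe"], self.junctions)
        write_vcf_bnd(
            paths["junctions_vcf"], self.junctions, self.contig, len(self.reference)
        )
        write_segment_table(paths["segments"], self.segments)
        write_fasta(paths["junction_seqs"], self.junction_seqs)
        truth = {
            "contig": self.contig,
            "contig_length": len(self.reference),
            "circular": self.walk.circular,
            "steps": [
                (
                    {"gap": True, "anchor": s.anchor}
                    if s.is_gap
                    else {
                        "start": s.interval.to_1based()[0],
                        "end": s.interval.to_1based()[1],
                        "inverted": s.inverted,
                    }
                )
                for s in self.walk.steps
            ],
            "junction_plans": [
                None
                if p is None
                else {
                    "microhomology": p.microhomology,
                    "insertion": None
                    if p.insertion is None
                    else {
                        "length": p.insertion.length,
                        "origin": p.insertion.origin,
                        "inverted": p.insertion.inverted,
                    },
                }
                for p in self.junction_plans
            ],
        }
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
        return paths


# ---------------------------------------------------------------- planting

def _derivative_endpoints(walk: DerivativeWalk):
    """Per novel join: ((bound_a, side_a), (bound_b, side_b)) in derivative
    order; None for an endpoint on a gap step."""
    out = []
    for i, j in walk.novel_joins():
        a, b = walk.steps[i], walk.steps[j]
        if a.is_gap:
            ea = None
        elif a.inverted:
            ea = (a.interval.start, Side.RIGHT)
        else:
            ea = (a.interval.end, Side.LEFT)
        if b.is_gap:
            eb = None
        elif b.inverted:
            eb = (b.interval.end, Side.LEFT)
        else:
            eb = (b.interval.start, Side.RIGHT)
        out.append((ea, eb))
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class _RefEditor:
    """Read/write reference bases through derivative-oriented flank views."""

    def __init__(self, seq: bytearray):
        self.seq = seq

    def _coord(self, endpoint, which: str, t: int) -> tuple[int, bool]:
        """Reference coordinate and complement flag for flank index ``t``.

        ``which``: 'beyond_a' (t grows away from the join past breakpoint
        1), 'flank_a' (t grows backwards from the join), 'flank_b' (t
        grows away from the join into kept sequence), 'beyond_b' (t grows
        backwards from the join on the reference side).
        """
        pos, side = endpoint
        if which in ("beyond_a", "flank_b"):
            if side == Side.LEFT and which == "beyond_a":
                return pos + t, False
            if side == Side.RIGHT and which == "beyond_a":
                return pos - 1 - t, True
            if side == Side.RIGHT and which == "flank_b":
                return pos + t, False
            return pos - 1 - t, True  # LEFT flank_b (inverted entry)
        # backwards-growing views
        if side == Side.LEFT and which == "flank_a":
            return pos - 1 - t, False
        if side == Side.RIGHT and which == "flank_a":
            return pos + t, True
        if side == Side.RIGHT and which == "beyond_b":
            return pos - 1 - t, False
        return pos + t, True  # LEFT beyond_b

    def get(self, endpoint, which: str, t: int) -> str:
        pos, comp = self._coord(endpoint, which, t)
        base = chr(self.seq[pos])
        return _COMP[base] if comp else base

    def set(self, endpoint, which: str, t: int, base: str) -> None:
        pos, comp = self._coord(endpoint, which, t)
        self.seq[pos] = ord(_COMP[base] if comp else base)

    def force_mismatch(self, ep1, which1, t1, ep2, which2, t2, rng) -> None:
        """Mutate the *reference-only* view (first argument) so the two
        derivative-oriented bases differ."""
        if self.get(ep1, which1, t1) == self.get(ep2, which2, t2):
            other = self.get(ep2, which2, t2)
            choices = [b for b in "ACGT" if b != other]
            self.set(ep1, which1, t1, choices[rng.integers(len(choices))])


def _plant_junctions(
    ref: bytearray,
    walk: DerivativeWalk,
    plans: Sequence[Optional[JunctionPlan]],
    rng: np.random.Generator,
) -> None:
    editor = _RefEditor(ref)
    for (ea, eb), plan in zip(_derivative_endpoints(walk), plans):
        if plan is None or ea is None or eb is None:
            continue
        m = plan.microhomology
        if plan.insertion is not None and m != 0:
            raise ValueError("a junction plan cannot have both an insert and homology")
        for t in range(m):
            editor.set(ea, "beyond_a", t, editor.get(eb, "flank_b", t))
        # make the homology exactly m: break the next base on the right and
        # the first base on the left (left homology is never planted)
        editor.force_mismatch(ea, "beyond_a", m, eb, "flank_b", m, rng)
        editor.force_mismatch(eb, "beyond_b", 0, ea, "flank_a", 0, rng)


def _insertion_seq(
    ref: bytearray,
    endpoint_a,
    plan: InsertPlan,
    rng: np.random.Generator,
    search_window: int = 2000,
) -> str:
    seq = ref.decode()
    pos = endpoint_a[0]
    if plan.origin == "templated":
        src_start = pos - plan.offset - plan.length
        if src_start < 0:
            raise ValueError("templated insert source before contig start")
        ins = seq[src_start : src_start + plan.length]
        return revcomp(ins) if plan.inverted else ins
    # nontemplated: random bases, re-drawn if they resemble either window
    near = seq[max(0, pos - search_window) : pos + search_window]
    for _ in range(50):
        ins = "".join(rng.choice(list("ACGT"), size=plan.length))
        if plan.length < 10 or (ins not in near and revcomp(ins) not in near):
            return ins
    raise RuntimeError("could not draw a nontemplated insert distinct from context")


def simulate_derivative(
    reference: str,
    walk: DerivativeWalk,
    junction_plans: Optional[Sequence[Optional[JunctionPlan]]] = None,
    contig: str = "chr21_toy",
    seed: int = 0,
    flank_window: int = 150,
) -> SimulatedDerivative:
    """Splice a derivative sequence realizing a truth walk.

    Junction plans (one per novel join, in order) request microhomology
    ``m`` — realized by mutating the reference flanks before splicing so
    both copies genuinely share ``m`` bases — or an insertion.  Truth
    junctions, segments, copy numbers and junction-spanning sequences are
    returned alongside.  Infeasible homology (``m`` beyond the flank
    window) is an error.
    """
    rng = np.random.default_rng(seed)
    njoins = walk.novel_joins()
    if junction_plans is None:
        junction_plans = [JunctionPlan() for _ in njoins]
    if len(junction_plans) != len(njoins):
        raise ValueError(
            f"{len(junction_plans)} junction plans for {len(njoins)} novel joins"
        )
    for p in junction_plans:
        if p is not None and p.microhomology > flank_window:
            raise ValueError(
                f"microhomology {p.microhomology} exceeds flank window {flank_window}"
            )

    ref = bytearray(reference.encode())
    _plant_junctions(ref, walk, junction_plans, rng)
    endpoints = _derivative_endpoints(walk)

    # inserted sequences per join
    inserts: list[str] = []
    for (ea, eb), plan in zip(endpoints, junction_plans):
        if plan is not None and plan.insertion is not None and ea is not None:
            inserts.append(_insertion_seq(ref, ea, plan.insertion, rng))
        else:
            inserts.append("")

    ref_str = ref.decode()
    novel_set = {pair[0]: k for k, pair in enumerate(walk.novel_joins())}

    pieces: list[str] = []
    join_positions: list[int] = []  # derivative offset of each novel join
    pos = 0
    for idx, step in enumerate(walk.steps):
        if step.is_gap:
            piece = "N" * GAP_FILL
        elif step.inverted:
            piece = revcomp(ref_str[step.interval.start : step.interval.end])
        else:
            piece = ref_str[step.interval.start : step.interval.end]
        pieces.append(piece)
        pos += len(piece)
        if idx in novel_set:
            k = novel_set[idx]
            join_positions.append(pos)
            if inserts[k]:
                pieces.append(inserts[k])
                pos += len(inserts[k])
    derivative = "".join(pieces)

    # junction-spanning sequences, sliced from the derivative itself
    junctions = junctions_from_walk(walk)
    junction_seqs: dict[str, str] = {}
    ktrav = [novel_set[i] for i, _ in walk.novel_joins()]
    for k, dpos in zip(ktrav, join_positions):
        ins_len = len(inserts[k])
        lo = dpos - flank_window
        hi = dpos + ins_len + flank_window
        if walk.circular:
            segpts = [derivative[i % len(derivative)] for i in range(lo, hi)]
            seqk = "".join(segpts)
        else:
            seqk = derivative[max(0, lo) : min(len(derivative), hi)]
        jid = junctions[k].id
        if "N" not in seqk:
            junction_seqs[jid] = seqk
            junctions[k].junction_seq = seqk

    graph = graph_from_walk(walk, len(ref_str))
    segments = segments_from_graph(graph)
    cn_total = [
        (iv, c + 1) for iv, c in zip(graph.atoms, graph.copies)
    ]
    return SimulatedDerivative(
        contig=contig,
        reference=ref_str,
        derivative=derivative,
        walk=walk,
        junctions=junctions,
        junction_plans=list(junction_plans),
        junction_seqs=junction_seqs,
        segments=segments,
        cn_total=cn_total,
    )


def verify_planted_homology(sim: SimulatedDerivative, flank_window: int = 150) -> None:
    """Self-check: recompute each planted microhomology from the final
    reference and assert it equals the plan (guards against plant collisions)."""
    reference = {sim.contig: sim.reference}
    from .signature import junction_flanks

    for jx, plan in zip(sim.junctions, sim.junction_plans):
        if plan is None or not jx.resolved or jx.gap_entry:
            continue
        fa, fb, ba, bb = junction_flanks(jx, reference, flank_window)
        m = microhomology(fa, fb, ba, bb)
        expect = plan.microhomology if plan.insertion is None else 0
        if plan.insertion is None and m != expect:
            raise AssertionError(
                f"junction {jx.id}: planted m={expect} but reference shows {m}"
            )


# --------------------------------------------------------------------------
# trio SNVs
# --------------------------------------------------------------------------

def _vcf_text(contig: str, length: int, sample: str, rows: list[dict]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for r in rows:
        gt = "/".join(map(str, r["gt"]))
        if r.get("ad") is not None:
            fmt, val = "GT:AD", f"{gt}:{r['ad'][0]},{r['ad'][1]}"
        else:
            fmt, val = "GT", gt
        lines.append(
            f"{contig}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
            f"{r['qual']:.0f}\tPASS\t.\t{fmt}\t{val}"
        )
    return "\n".join(lines) + "\n"


def simulate_trio_snvs(
    contig: str,
    contig_length: int,
    segments: Sequence[Segment],
    origin: str,
    sites_per_segment: int = 200,
    seed: int = 0,
    depth: int = 30,
    allelic_depth: bool = True,
    low_qual_fraction: float = 0.1,
    outdir=None,
) -> dict:
    """Trio genotype VCFs consistent with a parental origin of the CGR.

    For each segment, ``sites_per_segment`` phase-informative sites are
    drawn (half paternal-ALT, half maternal-ALT in expectation).  DEL
    segments transmit only the unaffected homolog's allele (the child
    appears homozygous); DUP segments carry the ``origin`` parent's
    haplotype twice, which shows as a 2/3 allele-dosage in the child AD
    field.  QUAL values land above the conventional filter except for a
    ``low_qual_fraction`` of deliberately failing sites.
    """
    if origin not in ("paternal", "maternal"):
        raise ValueError("origin must be 'paternal' or 'maternal'")
    rng = np.random.default_rng(seed)
    child_rows, father_rows, mother_rows, truth = [], [], [], []
    for seg in segments:
        iv = seg.interval
        n = min(sites_per_segment, iv.length() // 2)
        positions = np.sort(
            rng.choice(np.arange(iv.start + 1, iv.end + 1), size=n, replace=False)
        )
        for pos in positions:
            ref_b, alt_b = rng.choice(list("ACGT"), size=2, replace=False)
            alt_parent = "paternal" if rng.random() < 0.5 else "maternal"
            low = rng.random() < low_qual_fraction
            quals = (
                rng.uniform(20, 40, size=3) if low else rng.uniform(45, 99, size=3)
            )
            dosage = seg.dosage.value
            if dosage in ("DEL", "TELDEL"):
                # origin parent's homolog is deleted: child keeps the other
                remaining = "maternal" if origin == "paternal" else "paternal"
                rem_alt = alt_parent == remaining
                child_gt = (1, 1) if rem_alt else (0, 0)
                father_gt = (1, 1) if alt_parent == "paternal" else (0, 0)
                mother_gt = (1, 1) if alt_parent == "maternal" else (0, 0)
                ad_p = 1.0 if rem_alt else 0.0
                d = max(1, int(rng.poisson(depth / 2)))
                ad = (int(round(d * (1 - ad_p))), int(round(d * ad_p)))
            else:
                child_gt = (0, 1)
                father_gt = (1, 1) if alt_parent == "paternal" else (0, 0)
                mother_gt = (1, 1) if alt_parent == "maternal" else (0, 0)
                if dosage == "DUP":
                    # the origin parent's haplotype is present twice
                    p_alt = 2 / 3 if alt_parent == origin else 1 / 3
                    d = max(2, int(rng.poisson(depth * 1.5)))
                else:
                    p_alt = 0.5
                    d = max(2, int(rng.poisson(depth)))
                n_alt = int(rng.binomial(d, p_alt))
                ad = (d - n_alt, n_alt)
            row = {
                "pos": int(pos),
                "ref": ref_b,
                "alt": alt_b,
            }
            child_rows.append(
                row | {"gt": child_gt, "ad": ad if allelic_depth else None, "qual": quals[0]}
            )
            father_rows.append(row | {"gt": father_gt, "ad": None, "qual": quals[1]})
            mother_rows.append(row | {"gt": mother_gt, "ad": None, "qual": quals[2]})
            truth.append(
                {
                    "pos": int(pos),
                    "segment": seg.label,
                    "dosage": dosage,
                    "alt_parent": alt_parent,
                    "low_qual": bool(low),
                }
            )
    result = {
        "child": _vcf_text(contig, contig_length, "child", child_rows),
        "father": _vcf_text(contig, contig_length, "father", father_rows),
        "mother": _vcf_text(contig, contig_length, "mother", mother_rows),
        "truth": pd.DataFrame(truth),
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for who in ("child", "father", "mother"):
            (out / f"{who}.vcf").write_text(result[who])
        result["truth"].to_csv(out / "trio_truth.tsv", sep="\t", index=False)
        result["paths"] = {who: out / f"{who}.vcf" for who in ("child", "father", "mother")}
    return result


# --------------------------------------------------------------------------
# read depth
# --------------------------------------------------------------------------

def simulate_depth(
    contig: str,
    contig_length: int,
    cn_segments: Sequence[tuple[GenomicInterval, int]],
    coverage: float = 30.0,
    bin_size: int = 1000,
    read_length: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned mean depth under a Poisson read-count model.

    Expected depth in a bin of total copy number ``cn`` is
    ``coverage * cn / 2``; read counts are Poisson.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for start in range(0, contig_length, bin_size):
        end = min(start + bin_size, contig_length)
        mid = (start + end) // 2
        cn = 2
        for iv, c in cn_segments:
            if iv.start <= mid < iv.end:
                cn = c
                break
        lam = coverage * (cn / 2) * (end - start) / read_length
        reads = rng.poisson(lam)
        rows.append(
            {
                "contig": contig,
                "bin_start": start,
                "bin_end": end,
                "mean_depth": reads * read_length / (end - start),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# named scenarios
# --------------------------------------------------------------------------

def _steps(contig: str, items: list) -> list[WalkStep]:
    out = []
    for item in items:
        if item[0] == "gap":
            out.append(WalkStep(None, anchor=item[1]))
        else:
            s, e, inv = item
            out.append(WalkStep(GenomicInterval(contig, s, e), inv))
    return out


def _scenario_dup6(contig: str):
    """Six duplicated segments; a D-J-F(inv) cassette inserted on the short
    arm, a relocated inverted copy, and two in-place tandem gains."""
    length = 120_000
    walk = DerivativeWalk(
        _steps(
            contig,
            [
                (0, 10_000, False),
                (40_000, 43_000, False),   # D
                (60_000, 62_000, False),   # J
                (50_000, 54_000, True),    # F inverted
                (100_000, 110_000, False), # L copy
                (10_000, 76_000, False),
                (70_000, 76_000, False),   # B tandem gain
                (76_000, 92_000, False),
                (88_000, 92_000, False),   # H tandem gain
                (92_000, 120_000, False),
            ],
        )
    )
    plans = [
        JunctionPlan(microhomology=12),
        JunctionPlan(microhomology=1),
        JunctionPlan(microhomology=79),
        JunctionPlan(microhomology=5),
        JunctionPlan(microhomology=33),
        JunctionPlan(insertion=InsertPlan(length=4, origin="nontemplated")),
        JunctionPlan(microhomology=8),
    ]
    return length, walk, plans, "paternal"


def _scenario_ring21(contig: str):
    """Terminal deletions on both arms rescued by ring formation, with an
    inverted segment relocated next to retained short-arm material."""
    length = 100_000
    walk = DerivativeWalk(
        _steps(
            contig,
            [
                (20_000, 28_000, True),   # C inverted
                (3_000, 8_000, False),    # retained p material
                (35_000, 88_000, False),  # long retained block
                (90_000, 94_000, True),   # G inverted
            ],
        ),
        circular=True,
    )
    plans = [
        JunctionPlan(microhomology=2),
        JunctionPlan(insertion=InsertPlan(length=40, origin="templated", offset=300)),
        JunctionPlan(microhomology=0),  # blunt
        JunctionPlan(microhomology=5),
    ]
    return length, walk, plans, "maternal"


def _scenario_mixed13(contig: str):
    """Deletions plus direct and inverted duplications with one unresolved
    junction partner (an explicit gap in the derivative)."""
    length = 150_000
    walk = DerivativeWalk(
        _steps(
            contig,
            [
                (0, 20_000, False),
                (50_000, 55_000, True),    # inverted gain
                (70_000, 74_000, False),   # gain
                (25_000, 60_000, False),
                ("gap", 10_001),           # unresolved partner (1-based anchor)
                (90_000, 95_000, False),   # gain
                (65_000, 130_000, False),
                (110_000, 115_000, True),  # inverted gain
                (135_000, 150_000, False),
            ],
        )
    )
    plans = [
        JunctionPlan(microhomology=3),
        JunctionPlan(insertion=InsertPlan(length=6, origin="nontemplated")),
        JunctionPlan(microhomology=7),
        None,  # into the gap
        None,  # out of the gap
        JunctionPlan(microhomology=1),
        JunctionPlan(insertion=InsertPlan(length=30, origin="templated", inverted=True)),
        JunctionPlan(microhomology=4),
    ]
    return length, walk, plans, "paternal"


SCENARIOS = {
    "chromoanasynthesis_dup6": _scenario_dup6,
    "ring21": _scenario_ring21,
    "mixed_delsdups13": _scenario_mixed13,
}


def simulate_scenario(
    name: str,
    seed: int = 0,
    outdir=None,
    trio: bool = True,
    depth: bool = True,
    sites_per_segment: int = 200,
    coverage: float = 30.0,
    bin_size: int = 1000,
) -> dict:
    """Run one named scenario end to end; returns all truth artifacts."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(SCENARIOS)}")
    contig = "chr21_toy"
    length, walk, plans, origin = SCENARIOS[name](contig)
    reference = make_reference(length, seed)
    sim = simulate_derivative(reference, walk, plans, contig=contig, seed=seed + 1)
    verify_planted_homology(sim)
    result = {"name": name, "seed": seed, "sim": sim, "origin": origin}
    if outdir is not None:
        result["paths"] = sim.write(outdir)
    if trio:
        result["trio"] = simulate_trio_snvs(
            contig,
            length,
            sim.segments,
            origin,
            sites_per_segment=sites_per_segment,
            seed=seed + 2,
            outdir=None if outdir is None else Path(outdir) / "trio",
        )
    if depth:
        df = simulate_depth(
            contig, length, sim.cn_total, coverage=coverage, bin_size=bin_size,
            seed=seed + 3,
        )
        result["depth"] = df
        if outdir is not None:
            write_depth_tsv(Path(outdir) / "depth.tsv", df)
    return result


# --------------------------------------------------------------------------
# random walks (property tests and round-trips)
# --------------------------------------------------------------------------

def random_walk(
    rng: np.random.Generator,
    contig: str = "chr21_toy",
    contig_length: int = 50_000,
    max_events: int = 4,
    allow_ring: bool = False,
    allow_gap: bool = False,
    unit: int = 100,
) -> DerivativeWalk:
    """A random structurally valid derivative walk.

    Built by applying deletion / (possibly inverted, possibly dispersed)
    duplication / inversion events to the identity walk, on a ``unit``-nt
    lattice, keeping terminal anchors unless a ring is requested.
    """
    lo, hi = 2 * unit, contig_length - 2 * unit

    def rpos(a, b):
        return int(rng.integers(a // unit, b // unit)) * unit

    steps = [WalkStep(GenomicInterval(contig, 0, contig_length))]
    n_events = int(rng.integers(1, max_events + 1))
    for _ in range(n_events):
        op = rng.choice(["del", "dup", "inv"])
        # pick a host step to split (non-gap, long enough)
        hosts = [
            i
            for i, s in enumerate(steps)
            if not s.is_gap and s.interval.length() >= 8 * unit
        ]
        if not hosts:
            break
        i = int(hosts[rng.integers(len(hosts))])
        host = steps[i]
        a, b = host.interval.start, host.interval.end
        x = rpos(a + unit, b - 3 * unit)
        y = rpos(x + unit, b - unit)
        if host.inverted:
            continue  # edit only forward-oriented hosts; keeps coordinates simple
        left = WalkStep(GenomicInterval(contig, a, x))
        mid = WalkStep(GenomicInterval(contig, x, y))
        right = WalkStep(GenomicInterval(contig, y, b))
        if op == "del":
            steps[i : i + 1] = [left, right]
        elif op == "inv":
            steps[i : i + 1] = [left, WalkStep(mid.interval, True), right]
        else:  # dup: reinsert a copy of mid somewhere downstream
            inverted = bool(rng.random() < 0.5)
            copy = WalkStep(mid.interval, inverted)
            steps[i : i + 1] = [left, mid, right]
            j = int(rng.integers(i + 2, len(steps) + 1))
            steps.insert(j, copy)
    walk = DerivativeWalk(steps).normalized()
    if allow_gap and len(walk.steps) >= 3 and rng.random() < 0.5:
        k = int(rng.integers(1, len(walk.steps) - 1))
        anchor = int(rng.integers(lo, hi))
        walk.steps.insert(k, WalkStep(None, anchor=anchor))
    if allow_ring and len(walk.steps) >= 3 and rng.random() < 0.3:
        inner = walk.steps[1:-1]
        retains_end = any(
            not s.is_gap
            and (s.interval.contains(0) or s.interval.contains(contig_length - 1))
            for s in inner
        )
        if inner and not retains_end and not any(
            s.is_gap for s in (inner[0], inner[-1])
        ):
            walk = DerivativeWalk(inner, circular=True).normalized()
    return walk


__all__ = [
    "MIN_REFERENCE_LENGTH",
    "GAP_FILL",
    "InsertPlan",
    "JunctionPlan",
    "SimulatedDerivative",
    "make_reference",
    "simulate_derivative",
    "verify_planted_homology",
    "simulate_trio_snvs",
    "simulate_depth",
    "simulate_scenario",
    "random_walk",
    "SCENARIOS",
]
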