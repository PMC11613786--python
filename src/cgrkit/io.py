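"""Readers and writers for the on-disk formats.

Formats handled
---------------
* segment tables — TSV with columns ``Segment/Start/End/Type[/Method]``,
  1-based inclusive coordinates (``pter``/``qter`` accepted for the
  terminal positions); ``Type`` in {DEL, DUP, INV}; a ``Tel`` row is a
  terminal deletion (TELDEL);
* junction BEDPE — 10 standard columns plus optional ``seq`` and ``info``
  columns; strand encoding is the fixed mapping of :mod:`cgrkit.core`;
  an unresolved mate is written as ``.  -1  0`` with strand ``.``;
* minimal VCF 4.2 — BND records with bracket ALTs paired by MATEID, and
  SNV genotype records with GT/QUAL (optional AD) for trio phasing;
* depth TSV — ``contig  bin_start  bin_end  mean_depth`` (0-based
  half-open bins);
* FASTA via Biopython; JSON case bundles / reports.

Only the subset of VCF needed by the pipeline is supported: this code
consumes caller output, it is not a caller.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Breakpoint,
    Dosage,
    GenomicInterval,
    Junction,
    Segment,
    Side,
)

DEFAULT_MIN_QUAL = 40.0


# --------------------------------------------------------------------------
# packaged case data
# --------------------------------------------------------------------------

def load_case_data() -> dict:
    """The packaged chromosome-21 case-study tables and metadata."""
    with resources.files("cgrkit.data").joinpath("cases.json").open() as fh:
        return json.load(fh)


def packaged_segment_table(name: str) -> Path:
    return Path(str(resources.files("cgrkit.data").joinpath(name)))


# --------------------------------------------------------------------------
# segment tables
# --------------------------------------------------------------------------

_TYPE_MAP = {"DEL": Dosage.DEL, "DUP": Dosage.DUP, "INV": Dosage.INV, "NML": Dosage.NML}


def read_segment_table(
    path, case_id: str, contig: str = "chr21", contig_length: Optional[int] = None
) -> list[Segment]:
    """Read a segment TSV into Segments (in file order).

    Coordinates are 1-based inclusive; ``pter`` maps to 1 and ``qter`` to
    the contig length.  Rows labelled ``Tel`` become TELDEL.  A row with
    ``Start > End`` or an unknown ``Type`` is a hard error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"Segment", "Start", "End", "Type"}
    if not required.issubset(df.columns):
        raise ValueError(f"segment table {path} lacks columns {required - set(df.columns)}")
    segments: list[Segment] = []
    labels: set[str] = set()
    for idx, row in df.iterrows():
        label = str(row["Segment"]).strip()
        start = _parse_coord(row["Start"], contig_length, terminal="pter")
        end = _parse_coord(row["End"], contig_length, terminal="qter")
        if start > end:
            raise ValueError(
                f"segment table row {label!r} (line {idx + 2}): Start {start} > End {end}"
            )
        type_str = str(row["Type"]).strip().upper()
        if type_str not in _TYPE_MAP:
            raise ValueError(
                f"segment table row {label!r}: unknown Type {row['Type']!r}"
            )
        dosage = _TYPE_MAP[type_str]
        if label.lower() == "tel" and dosage == Dosage.DEL:
            dosage = Dosage.TELDEL
        if label in labels:
            raise ValueError(f"duplicate segment label {label!r} in {path}")
        labels.add(label)
        segments.append(
            Segment(
                label=label,
                interval=GenomicInterval.from_1based(contig, start, end),
                dosage=dosage,
                case_id=case_id,
                method=str(row.get("Method", "") or ""),
            )
        )
    return segments


def _parse_coord(value, contig_length: Optional[int], terminal: str) -> int:
    text = str(value).strip().replace(",", "")
    if text.lower() == "pter":
        return 1
    if text.lower() == "qter":
        if contig_length is None:
            raise ValueError("'qter' coordinate needs a contig length")
        return contig_length
    return int(text)


def write_segment_table(path, segments: Sequence[Segment]) -> None:
    rows = []
    for s in segments:
        s1, e1 = s.interval.to_1based()
        dosage = "DEL" if s.dosage == Dosage.TELDEL else s.dosage.value
        rows.append(
            {"Segment": s.label, "Start": s1, "End": e1, "Type": dosage, "Method": s.method}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# BEDPE junctions
# --------------------------------------------------------------------------

def _endpoint_to_bedpe(bp: Breakpoint) -> tuple[str, int, int, str]:
    if not bp.resolved or bp.position is None:
        return ".", -1, 0, "."
    if bp.side == Side.LEFT:
        if bp.position == 0:
            raise ValueError("LEFT-side breakpoint at contig start has no retained base")
        return bp.contig, bp.position - 1, bp.position, "+"
    return bp.contig, bp.position, bp.position + 1, "-"


def _strand2(bp: Breakpoint) -> str:
    # second mate uses the flipped strand convention (HT -> (+,+))
    if not bp.resolved or bp.position is None:
        return "."
    return "+" if bp.side == Side.RIGHT else "-"


def write_junctions_bedpe(path, junctions: Sequence[Junction]) -> None:
    lines = []
    for i, jx in enumerate(junctions):
        c1, s1, e1, st1 = _endpoint_to_bedpe(jx.bp1)
        c2, s2, e2, _ = _endpoint_to_bedpe(jx.bp2)
        st2 = _strand2(jx.bp2)
        name = jx.id or f"junction_{i + 1}"
        seq = jx.junction_seq or "."
        info = "gap_entry=1" if jx.gap_entry else "."
        lines.append(
            "\t".join(
                map(str, [c1, s1, e1, c2, s2, e2, name, ".", st1, st2, seq, info])
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_junctions_bedpe(path, contig_length: Optional[int] = None) -> list[Junction]:
    """Read junctions from BEDPE (strand columns decode the orientation)."""
    junctions: list[Junction] = []
    text = Path(path).read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not rows:
        warnings.warn(f"empty BEDPE file {path}", stacklevel=2)
        return junctions
    for lineno, line in enumerate(rows, start=1):
        f = line.rstrip("\n").split("\t")
        if len(f) < 10:
            raise ValueError(f"{path}:{lineno}: BEDPE needs >= 10 columns")
        bp1 = _bedpe_endpoint(f[0], f[1], f[2], f[8], mate=1, where=f"{path}:{lineno}")
        bp2 = _bedpe_endpoint(f[3], f[4], f[5], f[9], mate=2, where=f"{path}:{lineno}")
        for bp in (bp1, bp2):
            if bp.resolved and contig_length is not None and bp.position > contig_length:
                raise ValueError(
                    f"{path}:{lineno}: breakpoint {bp.position} beyond contig end"
                )
        seq = f[10] if len(f) > 10 and f[10] != "." else None
        info = f[11] if len(f) > 11 else "."
        junctions.append(
            Junction(
                bp1,
                bp2,
                junction_seq=seq,
                id=f[6] if f[6] != "." else "",
                gap_entry="gap_entry=1" in info,
            )
        )
    return junctions


def _bedpe_endpoint(chrom, start, end, strand, mate: int, where: str) -> Breakpoint:
    if chrom == "." or strand == ".":
        return Breakpoint(".", None, Side.LEFT, resolved=False)
    start, end = int(start), int(end)
    if strand not in "+-":
        raise ValueError(f"{where}: malformed strand {strand!r}")
    if mate == 1:
        side = Side.LEFT if strand == "+" else Side.RIGHT
    else:
        side = Side.RIGHT if strand == "+" else Side.LEFT
    boundary = end if side == Side.LEFT else start
    return Breakpoint(chrom, boundary, side)


# --------------------------------------------------------------------------
# VCF breakends
# --------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?P<t5>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<t3>[ACGTNacgtn]*)$"
)


def write_vcf_bnd(path, junctions: Sequence[Junction], contig: str, contig_length: int) -> None:
    """Write resolved junctions as paired VCF 4.2 BND records."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    records = []
    for i, jx in enumerate(junctions):
        if not jx.resolved:
            continue
        name = jx.id or f"bnd_{i + 1}"
        a, b = jx.bp1, jx.bp2
        records.append((a, b, f"{name}_1", f"{name}_2"))
        records.append((b, a, f"{name}_2", f"{name}_1"))
    for this, other, rid, mate in sorted(records, key=lambda r: (r[0].pos1, r[2])):
        alt = _bnd_alt(this, other)
        lines.append(
            f"{this.contig}\t{this.pos1}\t{rid}\tN\t{alt}\t.\tPASS\t"
            f"SVTYPE=BND;MATEID={mate}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _bnd_alt(this: Breakpoint, other: Breakpoint) -> str:
    p = f"{other.contig}:{other.pos1}"
    if this.side == Side.LEFT:
        return f"N[{p}[" if other.side == Side.RIGHT else f"N]{p}]"
    return f"]{p}]N" if other.side == Side.LEFT else f"[{p}[N"


def read_vcf_bnd(path) -> list[Junction]:
    """Read BND mate pairs from a VCF into junctions.

    Mates are paired by MATEID; unpaired breakends are reported and
    skipped.  A malformed bracket ALT is an error naming the record.
    """
    ends: dict[str, tuple[Breakpoint, Breakpoint, str]] = {}
    order: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if "SVTYPE" in rec.info and rec.info["SVTYPE"] != "BND":
                continue
            alt = rec.alts[0] if rec.alts else ""
            m = _BND_RE.match(alt)
            if not m:
                if any(c in alt for c in "[]"):
                    raise ValueError(
                        f"{path}: malformed bracket ALT {alt!r} in record "
                        f"{rec.id or rec.pos}"
                    )
                continue
            this_side = Side.LEFT if m.group("t5") else Side.RIGHT
            partner_side = Side.RIGHT if m.group("b1") == "[" else Side.LEFT
            this_bound = rec.pos if this_side == Side.LEFT else rec.pos - 1
            ppos = int(m.group("pos"))
            partner_bound = ppos if partner_side == Side.LEFT else ppos - 1
            this_bp = Breakpoint(rec.contig, this_bound, this_side)
            partner_bp = Breakpoint(m.group("chrom"), partner_bound, partner_side)
            mate = rec.info.get("MATEID")
            if isinstance(mate, tuple):
                mate = mate[0]
            rid = rec.id or f"{rec.contig}:{rec.pos}"
            ends[rid] = (this_bp, partner_bp, str(mate) if mate else "")
            order.append(rid)

    junctions: list[Junction] = []
    used: set[str] = set()
    for rid in order:
        if rid in used:
            continue
        this_bp, partner_bp, mate = ends[rid]
        if mate and mate in ends:
            mate_this, mate_partner, _ = ends[mate]
            if (mate_this.position, mate_this.side) != (
                partner_bp.position,
                partner_bp.side,
            ):
                warnings.warn(f"inconsistent mate pair {rid}/{mate}", stacklevel=2)
            used.update({rid, mate})
            jid = rid[:-2] if rid.endswith(("_1", "_2")) else rid
            junctions.append(Junction(this_bp, partner_bp, id=jid))
        else:
            used.add(rid)
            warnings.warn(f"unpaired breakend {rid} skipped", stacklevel=2)
    return junctions


# --------------------------------------------------------------------------
# trio SNV genotypes
# --------------------------------------------------------------------------

def _read_genotype_vcf(path) -> dict[tuple[str, int], dict]:
    sites = {}
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            call = rec.samples[sample]
            gt = call.get("GT")
            ad = call.get("AD")
            sites[(rec.contig, rec.pos)] = {
                "gt": tuple(gt) if gt is not None else None,
                "ad": tuple(ad) if ad is not None and ad[0] is not None else None,
                "qual": rec.qual,
            }
    return sites


def diploid_alt_parent(child_gt, father_gt, mother_gt) -> Optional[str]:
    """Which parent donated the child's ALT allele, if unambiguous.

    Only heterozygous children are informative under diploid logic; the
    ALT is paternal when the father carries it, the mother does not, and
    the mother can supply the REF allele (and symmetrically maternal).
    """
    if None in (child_gt, father_gt, mother_gt):
        return None
    if None in child_gt or None in father_gt or None in mother_gt:
        return None
    if set(child_gt) != {0, 1}:
        return None
    f_alt, m_alt = 1 in father_gt, 1 in mother_gt
    f_ref, m_ref = 0 in father_gt, 0 in mother_gt
    if f_alt and not m_alt and m_ref:
        return "paternal"
    if m_alt and not f_alt and f_ref:
        return "maternal"
    return None


def read_phased_snvs(
    path_child, path_father, path_mother, min_qual: float = DEFAULT_MIN_QUAL
) -> pd.DataFrame:
    """Collect phase-informative trio sites passing the quality filter.

    Keeps sites present in all three samples with QUAL strictly greater
    than ``min_qual`` in each; annotates each with the diploid-logic
    parent of the ALT allele (``paternal`` / ``maternal`` / None).
    Genotypes are retained so that dosage-aware logic (hemizygous
    segments, allele-dosage fractions) can be applied downstream.
    """
    child = _read_genotype_vcf(path_child)
    father = _read_genotype_vcf(path_father)
    mother = _read_genotype_vcf(path_mother)
    rows = []
    n_missing = 0
    for key in sorted(child, key=lambda k: (k[0], k[1])):
        if key not in father or key not in mother:
            continue
        c, f, m = child[key], father[key], mother[key]
        if c["gt"] is None or f["gt"] is None or m["gt"] is None:
            n_missing += 1
            continue
        quals = [c["qual"], f["qual"], m["qual"]]
        if any(q is None or q <= min_qual for q in quals):
            continue
        alt_parent = diploid_alt_parent(c["gt"], f["gt"], m["gt"])
        rows.append(
            {
                "contig": key[0],
                "pos": key[1],
                "qual": min(quals),
                "child_gt": c["gt"],
                "father_gt": f["gt"],
                "mother_gt": m["gt"],
                "child_ad": c["ad"],
                "alt_parent": alt_parent,
            }
        )
    if n_missing:
        warnings.warn(f"{n_missing} sites skipped for missing GT", stacklevel=2)
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


# --------------------------------------------------------------------------
# depth tables and FASTA
# --------------------------------------------------------------------------

def read_depth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["contig", "bin_start", "bin_end", "mean_depth"],
        header=0,
    )
    return df


def write_depth_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# walk JSON
# --------------------------------------------------------------------------

def walk_to_dict(walk, contig_length: Optional[int] = None) -> dict:
    """JSON-ready walk description (1-based inclusive step coordinates)."""
    from .core import DerivativeWalk  # noqa: F401  (type reference)

    steps = []
    for s in walk.steps:
        if s.is_gap:
            steps.append({"gap": True, "anchor": s.anchor, "inverted": s.inverted})
        else:
            s1, e1 = s.interval.to_1based()
            steps.append(
                {
                    "contig": s.interval.contig,
                    "start": s1,
                    "end": e1,
                    "inverted": s.inverted,
                }
            )
    return {
        "schema_version": 1,
        "circular": walk.circular,
        "contig_length": contig_length,
        "steps": steps,
        "junction_count": walk.junction_count(),
        "gaps": walk.gaps,
    }


def walk_from_dict(d: dict):
    from .core import DerivativeWalk, WalkStep

    steps = []
    for s in d["steps"]:
        if s.get("gap"):
            steps.append(WalkStep(None, anchor=s.get("anchor")))
        else:
            steps.append(
                WalkStep(
                    GenomicInterval.from_1based(s["contig"], s["start"], s["end"]),
                    s.get("inverted", False),
                )
            )
    return DerivativeWalk(steps, circular=d.get("circular", False))


def save_walk(path, walk, contig_length: Optional[int] = None) -> None:
    Path(path).write_text(
        json.dumps(walk_to_dict(walk, contig_length), indent=1, sort_keys=True)
    )


def load_walk(path):
    return walk_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# case bundles
# --------------------------------------------------------------------------

@dataclass
class CaseBundle:
    """One case's segments + junctions + nomenclature, as ingested."""

    case_id: str
    segments: list[Segment] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    karyotype_string: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        segs = []
        for s in self.segments:
            s1, e1 = s.interval.to_1based()
            segs.append(
                {
                    "label": s.label,
                    "contig": s.interval.contig,
                    "start": s1,
                    "end": e1,
                    "dosage": s.dosage.value,
                    "method": s.method,
                }
            )
        jxs = []
        for j in self.junctions:
            jxs.append(
                {
                    "id": j.id,
                    "contig1": j.bp1.contig,
                    "pos1": j.bp1.position,
                    "side1": j.bp1.side.value if j.bp1.resolved else None,
                    "resolved1": j.bp1.resolved,
                    "contig2": j.bp2.contig,
                    "pos2": j.bp2.position,
                    "side2": j.bp2.side.value if j.bp2.resolved else None,
                    "resolved2": j.bp2.resolved,
                    "gap_entry": j.gap_entry,
                    "junction_seq": j.junction_seq,
                }
            )
        return {
            "schema_version": 1,
            "case_id": self.case_id,
            "segments": segs,
            "junctions": jxs,
            "karyotype_string": self.karyotype_string,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseBundle":
        segments = [
            Segment(
                label=s["label"],
                interval=GenomicInterval.from_1based(s["contig"], s["start"], s["end"]),
                dosage=Dosage(s["dosage"]),
                case_id=d["case_id"],
                method=s.get("method", ""),
            )
            for s in d["segments"]
        ]
        junctions = []
        for j in d["junctions"]:
            bp1 = (
                Breakpoint(j["contig1"], j["pos1"], Side(j["side1"]))
                if j["resolved1"]
                else Breakpoint(".", None, Side.LEFT, resolved=False)
            )
            bp2 = (
                Breakpoint(j["contig2"], j["pos2"], Side(j["side2"]))
                if j["resolved2"]
                else Breakpoint(".", None, Side.LEFT, resolved=False)
            )
            junctions.append(
                Junction(
                    bp1,
                    bp2,
                    id=j.get("id", ""),
                    gap_entry=j.get("gap_entry", False),
                    junction_seq=j.get("junction_seq"),
                )
            )
        return cls(
            case_id=d["case_id"],
            segments=segments,
            junctions=junctions,
            karyotype_string=d.get("karyotype_string"),
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "CaseBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_case(case_id: str) -> CaseBundle:
    """Load one packaged chromosome-21 case study as a bundle."""
    data = load_case_data()
    if case_id not in data["cases"]:
        raise KeyError(f"unknown case {case_id!r}; have {sorted(data['cases'])}")
    meta = data["cases"][case_id]
    ref = data["reference"]
    segments = read_segment_table(
        packaged_segment_table(meta["segments"]),
        case_id,
        contig=ref["contig"],
        contig_length=ref["length"],
    )
    return CaseBundle(
        case_id=case_id,
        segments=segments,
        karyotype_string=meta["karyotype_seq"],
        metadata={
            "karyotype_cytoband": meta["karyotype_cytoband"],
            "assembly": ref["assembly"],
            "contig": ref["contig"],
            "contig_length": ref["length"],
            "centromere": ref["centromere"],
        },
    )


__all__ = [
    "CaseBundle",
    "DEFAULT_MIN_QUAL",
    "load_case",
    "load_case_data",
    "read_segment_table",
    "write_segment_table",
    "read_junctions_bedpe",
    "write_junctions_bedpe",
    "read_vcf_bnd",
    "write_vcf_bnd",
    "read_phased_snvs",
    "diploid_alt_parent",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_fasta",
    "write_fasta",
]
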