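"""Chimeric-construct confirmation, VCF (breakend) output and IGV session.

For every surviving candidate a chimeric reference construct is built from
the genome (up to 150 bp on each side of the junction), reads that match a
known transcript perfectly are set aside as normal transcription, the rest
are realigned to the constructs, and a read counts as supporting only when
its alignment spans at least ``min_span`` bases on both sides of the
junction. Confirmed events are emitted as paired VCF BND records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import pysam

from .discovery import BreakpointCandidate
from .filters import junction_windows, mrr
from .io import FastqRecord, write_fasta
from .models import revcomp

FLAG_SHORT_CONSTRUCT = "SHORT_CONSTRUCT"


@dataclass
class ChimericConstruct:
    construct_id: str
    sequence: str
    junction_index: int
    candidate: BreakpointCandidate
    flank5_length: int
    flank3_length: int


@dataclass
class SupportAlignment:
    read_id: str
    construct_id: str
    ref_start: int
    cigar: list[tuple[int, int]]     # pysam cigartuples
    sequence: str
    reverse: bool
    supporting: bool


@dataclass
class FusionCall:
    candidate: BreakpointCandidate
    construct: ChimericConstruct
    supporting_read_count: int
    supporting_read_ids: list[str]
    alignments: list[SupportAlignment] = field(default_factory=list)
    vcf_ids: tuple[str, str] = ("", "")


def remove_known_transcript_reads(
    reads: Sequence[FastqRecord],
    transcriptome: Mapping[str, str],
) -> list[FastqRecord]:
    """Drop reads matching some transcript end-to-end with zero mismatches.

    Such reads are ordinary transcription; junction-spanning reads can never
    match a single transcript perfectly and are always retained.
    """
    blob = "#".join(transcriptome[k] for k in sorted(transcriptome))
    blob = blob + "#" + revcomp(blob)
    return [r for r in reads if r.bases not in blob]


def build_construct(
    candidate: BreakpointCandidate,
    genome: Mapping[str, str],
    flank: int = 150,
    min_flank: int = 20,
    allowlist_genes: set[str] | frozenset[str] = frozenset(),
    construct_id: str | None = None,
) -> ChimericConstruct | None:
    """Genome-derived chimeric construct around the candidate junction.

    Flanks truncate at chromosome ends; a flank shorter than ``min_flank``
    rejects the construct (flag SHORT_CONSTRUCT). Same-gene candidates are
    built only for allowlisted genes.
    """
    if (
        candidate.gene5
        and candidate.gene5 not in ("", "NA")
        and candidate.gene5 == candidate.gene3
        and candidate.gene5 not in allowlist_genes
    ):
        return None
    c5, p5, s5 = candidate.breakpoint5
    c3, p3, s3 = candidate.breakpoint3
    chrom5, chrom3 = genome[c5], genome[c3]
    if s5 == "+":
        flank5 = chrom5[max(0, p5 - flank) : p5]
    else:
        flank5 = revcomp(chrom5[p5 - 1 : p5 - 1 + flank])
    if s3 == "+":
        flank3 = chrom3[p3 - 1 : p3 - 1 + flank]
    else:
        flank3 = revcomp(chrom3[max(0, p3 - flank) : p3])
    if len(flank5) < min_flank or len(flank3) < min_flank:
        candidate.filter_flags.add(FLAG_SHORT_CONSTRUCT)
        return None
    cid = construct_id or f"construct_{candidate.contig_id}"
    return ChimericConstruct(cid, flank5 + flank3, len(flank5), candidate,
                             len(flank5), len(flank3))


_CIG_RE = re.compile(r"(\d+)([=XIDM])")
_OP_TO_PYSAM = {"=": 0, "X": 0, "M": 0, "I": 1, "D": 2}  # collapse to M/I/D


def _cigartuples(cigar: str) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for num, op in _CIG_RE.findall(cigar):
        code = _OP_TO_PYSAM[op]
        if out and out[-1][0] == code:
            out[-1] = (code, out[-1][1] + int(num))
        else:
            out.append((code, int(num)))
    return out


def molecule_id(read_id: str) -> str:
    """Consensus pair id (mate suffix stripped) so one molecule counts once."""
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def count_support(
    reads: Sequence[FastqRecord],
    construct: ChimericConstruct,
    min_span: int = 10,
    min_identity: float = 0.9,
) -> tuple[int, list[SupportAlignment]]:
    """Distinct consensus molecules spanning the junction by >= min_span each side."""
    j = construct.junction_index
    alignments: list[SupportAlignment] = []
    supporters: set[str] = set()
    for rec in reads:
        best = None
        for rev, seq in ((False, rec.bases), (True, revcomp(rec.bases))):
            res = edlib.align(seq, construct.sequence, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            if best is None or res["editDistance"] < best[0]["editDistance"]:
                best = (res, rev, seq)
        if best is None:
            continue
        res, rev, seq = best
        s, e = min(res["locations"])
        e += 1
        alen = e - s
        identity = 1.0 - res["editDistance"] / max(alen, 1)
        if identity < min_identity:
            continue
        supporting = s <= j - min_span and e >= j + min_span
        alignments.append(
            SupportAlignment(rec.read_id, construct.construct_id, s,
                             _cigartuples(res["cigar"]), seq, rev, supporting)
        )
        if supporting:
            supporters.add(molecule_id(rec.read_id))
    support_ids = sorted(supporters)
    return len(support_ids), alignments


def confirm_candidates(
    candidates: Sequence[BreakpointCandidate],
    genome: Mapping[str, str],
    reads: Sequence[FastqRecord],
    transcriptome: Mapping[str, str],
    flank: int = 150,
    min_span: int = 10,
    min_support: int = 1,
    min_identity: float = 0.9,
    allowlist_genes: set[str] | frozenset[str] = frozenset(),
) -> list[FusionCall]:
    """Full confirmation pass; returns calls with SR >= min_support."""
    retained = remove_known_transcript_reads(reads, transcriptome)
    calls: list[FusionCall] = []
    ordered = sorted(candidates, key=lambda c: (c.breakpoint5, c.breakpoint3, c.contig_id))
    for n, cand in enumerate(ordered):
        construct = build_construct(
            cand, genome, flank=flank,
            allowlist_genes=allowlist_genes,
            construct_id=f"construct{n + 1:03d}",
        )
        if construct is None:
            continue
        count, alignments = count_support(retained, construct,
                                          min_span=min_span,
                                          min_identity=min_identity)
        if count >= min_support:
            cand.supporting_read_count = count
            ids = sorted(
                {molecule_id(a.read_id) for a in alignments if a.supporting}
            )
            cand.supporting_read_ids = ids
            calls.append(FusionCall(cand, construct, count, ids,
                                    [a for a in alignments if a.supporting]))
    return calls


# ---------------------------------------------------------------------------
# VCF breakend output


def _bnd_alt(ref_base: str, u_right: bool, v_chrom: str, v_pos: int,
             v_left: bool) -> str:
    p = f"{v_chrom}:{v_pos}"
    if u_right:
        return f"{ref_base}[{p}[" if v_left else f"{ref_base}]{p}]"
    return f"]{p}]{ref_base}" if not v_left else f"[{p}[{ref_base}"


def emit_vcf(
    calls: Sequence[FusionCall],
    genome: Mapping[str, str],
    mrr_window: int = 20,
) -> str:
    """VCF 4.2 text: two MATEID-linked BND records per call, sorted."""
    chrom_order = {c: i for i, c in enumerate(sorted(genome))}
    header = ["##fileformat=VCFv4.2", "##source=fusionforge"]
    for c in sorted(genome):
        header.append(f"##contig=<ID={c},length={len(genome[c])}>")
    for info_id, num, typ, desc in [
        ("SVTYPE", "1", "String", "Type of structural variant"),
        ("MATEID", "1", "String", "ID of mate breakend"),
        ("GENE5", "1", "String", "5-prime partner gene"),
        ("GENE3", "1", "String", "3-prime partner gene"),
        ("EXON5", "1", "String", "5-prime exon label"),
        ("EXON3", "1", "String", "3-prime exon label"),
        ("FRAME", "1", "String", "Reading frame status"),
        ("SR", "1", "Integer", "Supporting consensus reads"),
        ("CONTIG", "1", "String", "Assembled contig id"),
        ("MRR5", "1", "Float", "Mononucleotide repeat ratio, 5-prime junction flank"),
        ("MRR3", "1", "Float", "Mononucleotide repeat ratio, 3-prime junction flank"),
    ]:
        header.append(
            f'##INFO=<ID={info_id},Number={num},Type={typ},Description="{desc}">'
        )
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    rows = []
    for n, call in enumerate(sorted(
        calls, key=lambda c: (c.candidate.breakpoint5, c.candidate.breakpoint3)
    )):
        cand = call.candidate
        ann = cand.annotation
        c5, p5, s5 = cand.breakpoint5
        c3, p3, s3 = cand.breakpoint3
        id5, id3 = f"FUS{n + 1}_1", f"FUS{n + 1}_2"
        call.vcf_ids = (id5, id3)
        left, right = junction_windows(cand, mrr_window)
        mrr5 = mrr(left) if left else 0.0
        mrr3 = mrr(right) if right else 0.0
        common = (
            f"GENE5={cand.gene5 or 'NA'};GENE3={cand.gene3 or 'NA'};"
            f"EXON5={ann.label5 if ann else 'NA'};EXON3={ann.label3 if ann else 'NA'};"
            f"FRAME={ann.frame_status if ann else 'Indeterminate'};"
            f"SR={call.supporting_read_count};CONTIG={cand.contig_id};"
            f"MRR5={mrr5:.4f};MRR3={mrr3:.4f}"
        )
        ref5 = genome[c5][p5 - 1] if 0 < p5 <= len(genome[c5]) else "N"
        ref3 = genome[c3][p3 - 1] if 0 < p3 <= len(genome[c3]) else "N"
        u_right = s5 == "+"
        v_left = s3 == "+"
        alt5 = _bnd_alt(ref5, u_right, c3, p3, v_left)
        # mate record: junction side of bp3 is left when strand3 is '+'
        alt3 = _bnd_alt(ref3, not v_left, c5, p5, not u_right)
        rows.append((chrom_order[c5], p5, c5, id5, ref5, alt5,
                     f"SVTYPE=BND;MATEID={id3};{common}"))
        rows.append((chrom_order[c3], p3, c3, id3, ref3, alt3,
                     f"SVTYPE=BND;MATEID={id5};{common}"))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    body = [
        f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}"
        for _, pos, chrom, rid, ref, alt, info in rows
    ]
    return "\n".join(header + body) + "\n"


def write_vcf(calls: Sequence[FusionCall], genome: Mapping[str, str],
              path: str | Path, mrr_window: int = 20) -> None:
    Path(path).write_text(emit_vcf(calls, genome, mrr_window=mrr_window))


# ---------------------------------------------------------------------------
# IGV session


def igv_session(calls: Sequence[FusionCall], out_dir: str | Path) -> dict | None:
    """Write constructs.fa(.fai), sorted/indexed support.bam and session XML.

    Returns the written paths, or None (success) for an empty call set.
    """
    if not calls:
        return None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "constructs.fa"
    bam = out / "support.bam"
    xml = out / "igv_session.xml"

    constructs = {c.construct.construct_id: c.construct.sequence for c in calls}
    write_fasta(constructs, fasta)
    pysam.faidx(str(fasta))

    names = sorted(constructs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(constructs[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    unsorted = out / "support.unsorted.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bh:
        records = []
        for call in calls:
            for aln in call.alignments:
                a = pysam.AlignedSegment()
                a.query_name = aln.read_id
                a.query_sequence = aln.sequence
                a.reference_id = tid[aln.construct_id]
                a.reference_start = aln.ref_start
                a.cigartuples = aln.cigar
                a.mapping_quality = 60
                a.flag = 16 if aln.reverse else 0
                records.append(a)
        records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
        for a in records:
            bh.write(a)
    pysam.sort("-o", str(bam), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam))

    from xml.etree import ElementTree as ET

    session = ET.Element("Session", genome="constructs.fa", version="8")
    resources = ET.SubElement(session, "Resources")
    ET.SubElement(resources, "Resource", path="support.bam")
    panel = ET.SubElement(session, "Panel", name="DataPanel")
    ET.SubElement(panel, "Track", id="support.bam", name="Supporting reads")
    ET.ElementTree(session).write(str(xml), xml_declaration=True, encoding="utf-8")
    return {"fasta": fasta, "bam": bam, "session": xml}
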