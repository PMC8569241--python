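"""Breakpoint annotation: gene/exon labels and reading-frame status.

A breakpoint is snapped to the nearest exon boundary within a small
tolerance (Exon-exon_boundary), otherwise classified Mid-exon or Intronic.
Labels follow the ``strand|End_Ek|gene|transcript`` convention with exon
numbers in transcription order. Frame status compares the number of coding
bases retained from the 5' partner (L5) with the coding phase at the 3'
acceptor (P3): the fusion is In-frame iff L5 mod 3 == P3, meaning the 3'
gene is translated without a frame shift. Junction micro-insertions do not
enter the arithmetic — frame is computed from genomic breakpoints only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .discovery import BreakpointCandidate
from .models import TranscriptModel

LOC_BOUNDARY = "Exon-exon_boundary"
LOC_MID_EXON = "Mid-exon"
LOC_INTRONIC = "Intronic"

FRAME_IN = "In-frame"
FRAME_OUT = "Out-of-frame"
FRAME_NA = "Indeterminate"


@dataclass
class SideAnnotation:
    transcript: TranscriptModel | None
    exon_number: int | None
    boundary_kind: str | None          # "Start" or "End" (transcription order)
    location_class: str
    snapped_pos: int | None            # genomic 1-based boundary position


@dataclass
class FusionAnnotation:
    location_class: str
    frame_status: str
    label5: str
    label3: str
    exon5: int | None = None
    exon3: int | None = None


def format_label(strand: str, kind: str, exon: int, gene: str, transcript: str) -> str:
    return f"{strand}|{kind}_E{exon}|{gene}|{transcript}"


def parse_label(label: str) -> tuple[str, str, int, str, str]:
    strand, kind_exon, gene, transcript = label.split("|")
    kind, exon = kind_exon.split("_E")
    return strand, kind, int(exon), gene, transcript


def _pick_transcript(
    models: Sequence[TranscriptModel], chrom: str, pos: int, tolerance: int
) -> TranscriptModel | None:
    """Transcript containing (or within tolerance of) the breakpoint;
    canonical first, then longest CDS, then id."""
    inside = [
        t for t in models
        if t.chromosome == chrom and t.span[0] - tolerance <= pos <= t.span[1] + tolerance
    ]
    if not inside:
        return None
    return min(inside, key=lambda t: (not t.canonical, -t.cds_length, t.transcript_id))


def locate(
    breakpoint: tuple[str, int, str],
    transcript_models: Sequence[TranscriptModel],
    tolerance: int = 3,
) -> SideAnnotation:
    """Classify one breakpoint against the transcript models."""
    chrom, pos, _strand = breakpoint
    tx = _pick_transcript(transcript_models, chrom, pos, tolerance)
    if tx is None:
        return SideAnnotation(None, None, None, LOC_INTRONIC, None)
    # nearest exon boundary in transcription order
    best = None
    for gi, (s, e) in enumerate(tx.exons):
        number = tx.exon_number(gi)
        for gpos, genomic_edge in ((s, "left"), (e, "right")):
            if tx.strand == "+":
                kind = "Start" if genomic_edge == "left" else "End"
            else:
                kind = "End" if genomic_edge == "left" else "Start"
            d = abs(pos - gpos)
            cand = (d, number, kind, gpos)
            if best is None or cand < best:
                best = cand
    d, number, kind, gpos = best
    if d <= tolerance:
        return SideAnnotation(tx, number, kind, LOC_BOUNDARY, gpos)
    for gi, (s, e) in enumerate(tx.exons):
        if s <= pos <= e:
            return SideAnnotation(tx, tx.exon_number(gi), None, LOC_MID_EXON, pos)
    return SideAnnotation(tx, None, None, LOC_INTRONIC, None)


def _coding_bases_to(tx: TranscriptModel, genomic_pos: int) -> int | None:
    """CDS bases retained from the CDS start through ``genomic_pos`` (L5)."""
    cds0 = tx.cds_start_tx()
    if cds0 is None:
        return None
    off = tx.genomic_to_tx(genomic_pos)
    if off is None:
        return None
    return max(0, off - cds0 + 1)


def _acceptor_phase(tx: TranscriptModel, genomic_pos: int) -> int | None:
    """Coding phase P3 at the 3' acceptor base (0, 1 or 2)."""
    cds0 = tx.cds_start_tx()
    if cds0 is None:
        return None
    off = tx.genomic_to_tx(genomic_pos)
    if off is None or off < cds0:
        return None
    return (off - cds0) % 3


def frame_status(
    side5: SideAnnotation, side3: SideAnnotation
) -> str:
    """In-frame iff the retained 5' CDS length mod 3 equals the 3' phase."""
    if side5.location_class != LOC_BOUNDARY or side3.location_class != LOC_BOUNDARY:
        return FRAME_NA
    t5, t3 = side5.transcript, side3.transcript
    if t5 is None or t3 is None or t5.cds_start is None or t3.cds_start is None:
        return FRAME_NA
    l5 = _coding_bases_to(t5, side5.snapped_pos)
    p3 = _acceptor_phase(t3, side3.snapped_pos)
    if l5 is None or l5 <= 0 or p3 is None:
        return FRAME_NA
    return FRAME_IN if l5 % 3 == p3 else FRAME_OUT


def orient_candidate(
    candidate: BreakpointCandidate,
    models: Sequence[TranscriptModel],
    tolerance: int = 3,
) -> BreakpointCandidate:
    """Orient a candidate along the transcription direction of its genes.

    Contig orientation is arbitrary, so the same fusion can surface with the
    5'/3' roles swapped and all strands inverted. When the alignment strands
    disagree with the strands of the genes at both breakpoints, the
    reverse-complement representation is the transcript-sense one.
    """
    from .discovery import flipped

    t5 = _pick_transcript(models, candidate.breakpoint5[0],
                          candidate.breakpoint5[1], tolerance)
    t3 = _pick_transcript(models, candidate.breakpoint3[0],
                          candidate.breakpoint3[1], tolerance)
    votes = []
    if t5 is not None:
        votes.append(t5.strand != candidate.breakpoint5[2])
    if t3 is not None:
        votes.append(t3.strand != candidate.breakpoint3[2])
    if votes and all(votes):
        return flipped(candidate)
    return candidate


def annotate(
    candidate: BreakpointCandidate,
    models: Sequence[TranscriptModel],
    tolerance: int = 3,
) -> FusionAnnotation:
    """Compose locate + frame_status and attach the result to the candidate."""
    side5 = locate(candidate.breakpoint5, models, tolerance)
    side3 = locate(candidate.breakpoint3, models, tolerance)

    def _label(side: SideAnnotation, default_kind: str) -> str:
        if side.transcript is None:
            return "NA"
        kind = side.boundary_kind or default_kind
        exon = side.exon_number if side.exon_number is not None else 0
        return format_label(side.transcript.strand, kind, exon,
                            side.transcript.gene, side.transcript.transcript_id)

    if side5.location_class == LOC_BOUNDARY and side3.location_class == LOC_BOUNDARY:
        loc = LOC_BOUNDARY
    elif LOC_MID_EXON in (side5.location_class, side3.location_class):
        loc = LOC_MID_EXON
    else:
        loc = LOC_INTRONIC
    ann = FusionAnnotation(
        location_class=loc,
        frame_status=frame_status(side5, side3),
        label5=_label(side5, "End"),
        label3=_label(side3, "Start"),
        exon5=side5.exon_number,
        exon3=side3.exon_number,
    )
    candidate.annotation = ann
    candidate.gene5 = side5.transcript.gene if side5.transcript else "NA"
    candidate.gene3 = side3.transcript.gene if side3.transcript else "NA"
    return ann
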