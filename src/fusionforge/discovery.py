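"""Split alignment of contigs to the genome and breakpoint candidate calling.

Contigs are aligned with exact k-mer seeds grouped by diagonal and extended
with an x-drop heuristic; a contig producing two non-contiguous segments
(different chromosomes, a strand change, or a genomic gap beyond intron
scale) that tile the contig around a junction becomes a breakpoint
candidate. Redundant candidates from overlapping contigs are collapsed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assembly import Contig
from .models import revcomp
from .seedalign import KmerIndex, encode_seq, kmer_codes


@dataclass
class SegmentAlignment:
    contig_id: str
    contig_start: int            # 0-based half-open on the original contig
    contig_end: int
    chromosome: str
    genome_start: int            # 0-based half-open on the genome
    genome_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start

    def genomic_at(self, contig_pos: int) -> int:
        """Genomic 0-based position of one contig base inside the segment."""
        if not self.contig_start <= contig_pos < self.contig_end:
            raise IndexError("contig position outside segment")
        if self.strand == "+":
            return self.genome_start + (contig_pos - self.contig_start)
        return self.genome_end - 1 - (contig_pos - self.contig_start)


@dataclass
class BreakpointCandidate:
    contig_id: str
    contig_sequence: str
    junction_offset: int
    segment5: SegmentAlignment
    segment3: SegmentAlignment
    breakpoint5: tuple[str, int, str]        # (chrom, 1-based pos, strand)
    breakpoint3: tuple[str, int, str]
    filter_flags: set[str] = field(default_factory=set)
    annotation: object | None = None
    member_contig_ids: list[str] = field(default_factory=list)
    gene5: str = ""
    gene3: str = ""
    supporting_read_count: int = 0
    supporting_read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_contig_ids:
            self.member_contig_ids = [self.contig_id]


class GenomeIndex(KmerIndex):
    """K-mer index over genome chromosomes (thin alias for clarity)."""


def _xdrop_extend(q: str, r: str, qs: int, qe: int, gs: int,
                  xdrop: int = 8) -> tuple[int, int, int, int]:
    """Extend an exact-seed run [qs, qe) on one diagonal in both directions.

    Returns the extended (qs, qe, gs, ge) with match +1 / mismatch −3 x-drop
    scoring on each side.
    """
    diag = gs - qs
    # left
    score = best = 0
    best_q = qs
    qq = qs - 1
    while qq >= 0 and qq + diag >= 0:
        score += 1 if q[qq] == r[qq + diag] else -3
        if score > best:
            best, best_q = score, qq
        if score < best - xdrop:
            break
        qq -= 1
    new_qs = best_q
    # right
    score = best = 0
    best_q = qe
    qq = qe
    while qq < len(q) and qq + diag < len(r):
        score += 1 if q[qq] == r[qq + diag] else -3
        if score > best:
            best, best_q = score, qq + 1
        if score < best - xdrop:
            break
        qq += 1
    new_qe = best_q
    return new_qs, new_qe, new_qs + diag, new_qe + diag


def _identity(q: str, r: str, qs: int, qe: int, gs: int) -> float:
    n = qe - qs
    if n <= 0:
        return 0.0
    mism = sum(q[qs + i] != r[gs + i] for i in range(n))
    return 1.0 - mism / n


def split_align(
    contig: Contig,
    genome: Mapping[str, str],
    index: GenomeIndex,
    min_segment: int = 25,
    min_identity: float = 0.9,
    max_seed_gap: int = 50,
) -> list[SegmentAlignment]:
    """All well-supported local segments of a contig on the genome (both strands)."""
    k = index.k
    if len(contig.sequence) < k:
        warnings.warn(f"contig {contig.contig_id} shorter than k={k}; skipped")
        return []
    segments: list[SegmentAlignment] = []
    L = len(contig.sequence)
    for strand, oriented in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
        hits = index.seed_hits(oriented)
        for ri, pairs in sorted(hits.items()):
            chrom = index.names[ri]
            ref = genome[chrom]
            by_diag: dict[int, list[int]] = {}
            for qpos, rpos in pairs:
                by_diag.setdefault(rpos - qpos, []).append(qpos)
            for diag, qlist in sorted(by_diag.items()):
                qlist.sort()
                runs: list[tuple[int, int]] = []
                rs = prev = qlist[0]
                for qp in qlist[1:]:
                    if qp - prev > max_seed_gap:
                        runs.append((rs, prev + k))
                        rs = qp
                    prev = qp
                runs.append((rs, prev + k))
                intervals: list[tuple[int, int]] = []
                for qs, qe in runs:
                    eqs, eqe, _, _ = _xdrop_extend(oriented, ref, qs, qe, qs + diag)
                    if not intervals or eqs > intervals[-1][1]:
                        intervals.append((eqs, eqe))
                    else:  # merge overlap on the same diagonal
                        intervals[-1] = (intervals[-1][0], max(intervals[-1][1], eqe))
                for qs, qe in intervals:
                    if qe - qs < min_segment:
                        continue
                    ident = _identity(oriented, ref, qs, qe, qs + diag)
                    if ident < min_identity:
                        continue
                    if strand == "+":
                        cs, ce = qs, qe
                    else:
                        cs, ce = L - qe, L - qs
                    segments.append(
                        SegmentAlignment(contig.contig_id, cs, ce, chrom,
                                         qs + diag, qe + diag, strand, ident)
                    )
    segments.sort(key=lambda s: (s.contig_start, s.contig_end, s.chromosome,
                                 s.genome_start, s.strand))
    return segments


def _junction_gap(a: SegmentAlignment, b: SegmentAlignment) -> int | None:
    """Genomic distance between the adjacent ends of two same-chromosome,
    same-strand segments; None when not comparable."""
    if a.chromosome != b.chromosome or a.strand != b.strand:
        return None
    ga = a.genomic_at(a.contig_end - 1)
    gb = b.genomic_at(b.contig_start)
    return abs(gb - ga) - 1


def call_candidates(
    contig: Contig,
    segments: Sequence[SegmentAlignment],
    min_genomic_gap: int = 10000,
    max_contig_gap: int = 10,
    max_contig_overlap: int = 10,
) -> list[BreakpointCandidate]:
    """Breakpoint candidates from ordered segment pairs tiling one contig.

    A pair qualifies when the two segments abut on the contig (gap <=
    ``max_contig_gap``, overlap <= ``max_contig_overlap``) and cover
    non-contiguous genomic regions: different chromosomes, a strand change,
    or a same-strand genomic gap beyond ``min_genomic_gap`` (intron-scale
    gaps are ordinary splicing, not fusions).
    """
    out: list[BreakpointCandidate] = []
    segs = sorted(segments, key=lambda s: (s.contig_start, s.contig_end,
                                           s.chromosome, s.genome_start))
    for a in segs:
        for b in segs:
            if a is b or b.contig_start < a.contig_start:
                continue
            gap = b.contig_start - a.contig_end
            if gap > max_contig_gap or -gap > max_contig_overlap:
                continue
            noncontig = (
                a.chromosome != b.chromosome
                or a.strand != b.strand
                or (_junction_gap(a, b) or 0) > min_genomic_gap
            )
            if not noncontig:
                continue
            # overlapping segments = junction micro-homology; split the
            # ambiguity window down the middle
            if gap >= 0:
                junction = a.contig_end
            else:
                junction = (b.contig_start + a.contig_end) // 2
            bp5_pos = a.genomic_at(min(junction - 1, a.contig_end - 1))
            bp3_pos = b.genomic_at(max(junction, b.contig_start))
            out.append(
                BreakpointCandidate(
                    contig_id=contig.contig_id,
                    contig_sequence=contig.sequence,
                    junction_offset=junction,
                    segment5=a,
                    segment3=b,
                    breakpoint5=(a.chromosome, bp5_pos + 1, a.strand),
                    breakpoint3=(b.chromosome, bp3_pos + 1, b.strand),
                )
            )
    return out


def flipped(cand: BreakpointCandidate) -> BreakpointCandidate:
    """The same junction represented on the opposite contig strand.

    Assembled contigs have arbitrary orientation, so every candidate has an
    equivalent reverse-complement representation with the 5'/3' roles
    swapped and all strands inverted.
    """
    L = len(cand.contig_sequence)

    def flip_seg(s: SegmentAlignment) -> SegmentAlignment:
        return SegmentAlignment(
            s.contig_id, L - s.contig_end, L - s.contig_start, s.chromosome,
            s.genome_start, s.genome_end, "-" if s.strand == "+" else "+",
            s.identity,
        )

    def flip_bp(bp: tuple[str, int, str]) -> tuple[str, int, str]:
        return (bp[0], bp[1], "-" if bp[2] == "+" else "+")

    return BreakpointCandidate(
        contig_id=cand.contig_id,
        contig_sequence=revcomp(cand.contig_sequence),
        junction_offset=L - cand.junction_offset,
        segment5=flip_seg(cand.segment3),
        segment3=flip_seg(cand.segment5),
        breakpoint5=flip_bp(cand.breakpoint3),
        breakpoint3=flip_bp(cand.breakpoint5),
        filter_flags=set(cand.filter_flags),
        member_contig_ids=list(cand.member_contig_ids),
    )


def _bp_close(x: tuple[str, int, str], y: tuple[str, int, str], window: int) -> bool:
    return x[0] == y[0] and x[2] == y[2] and abs(x[1] - y[1]) <= window


def collapse_redundant(
    candidates: Sequence[BreakpointCandidate],
    merge_window: int = 5,
) -> list[BreakpointCandidate]:
    """Merge candidates whose breakpoint pairs agree within ``merge_window``
    on both sides; the candidate from the longest contig represents the
    group and records all member contig ids."""
    order = sorted(
        candidates,
        key=lambda c: (-len(c.contig_sequence), c.contig_id, c.breakpoint5, c.breakpoint3),
    )
    kept: list[BreakpointCandidate] = []
    for cand in order:
        merged = False
        for rep in kept:
            if _bp_close(cand.breakpoint5, rep.breakpoint5, merge_window) and _bp_close(
                cand.breakpoint3, rep.breakpoint3, merge_window
            ):
                for cid in cand.member_contig_ids:
                    if cid not in rep.member_contig_ids:
                        rep.member_contig_ids.append(cid)
                merged = True
                break
        if not merged:
            kept.append(cand)
    kept.sort(key=lambda c: (c.breakpoint5, c.breakpoint3, c.contig_id))
    return kept
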