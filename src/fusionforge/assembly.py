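"""Greedy overlap-layout-consensus assembly of reduced reads, per gene bin.

Repeatedly merges the contig pair with the longest suffix-prefix overlap of
at least ``min_overlap`` bases at identity >= ``min_identity``
(substitution-only overlap model), considering both orientations, until no
merge is possible; contained reads are absorbed. After layout, every contig
is polished by per-position majority vote over its member reads, so isolated
sequencing errors surviving UMI consensus are corrected wherever coverage
allows. Singleton reads are emitted as contigs so a lone junction-spanning
read still reaches breakpoint discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .models import revcomp

_ANCHOR = 12


@dataclass
class Contig:
    contig_id: str
    gene: str
    sequence: str
    member_read_ids: list[str] = field(default_factory=list)

    @property
    def member_count(self) -> int:
        return len(self.member_read_ids)


@dataclass
class _Member:
    read_id: str
    offset: int          # placement of the read on the fragment
    rc: bool


@dataclass
class _Frag:
    cid: str
    seq: str
    members: list[_Member]


def _overlap_candidates(a: str, b: str, min_overlap: int) -> set[int]:
    """Candidate suffix(a)/prefix(b) overlap lengths proposed by exact anchors.

    An anchor is a short exact block from b's prefix located inside a; with a
    substitution-only error model true overlaps almost always contain at
    least one clean anchor. The anchor never exceeds the minimum overlap, so
    short exact overlaps are still proposed.
    """
    cands: set[int] = set()
    la = len(a)
    w = max(4, min(_ANCHOR, min_overlap))
    for off in (0, w, 2 * w):
        if off + w > len(b):
            break
        probe = b[off : off + w]
        start = 0
        while True:
            i = a.find(probe, start)
            if i < 0:
                break
            cands.add(la - i + off)
            start = i + 1
    return cands


def _mismatches(x: str, y: str, budget: int) -> int:
    mism = 0
    for p, q in zip(x, y):
        if p != q:
            mism += 1
            if mism > budget:
                return mism
    return mism


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest acceptable suffix(a)-prefix(b) overlap length (0 if none)."""
    best = 0
    for ov in sorted(_overlap_candidates(a, b, min_overlap), reverse=True):
        if ov < min_overlap or ov > min(len(a), len(b)) or ov <= best:
            continue
        budget = int((1.0 - min_identity) * ov)
        if _mismatches(a[len(a) - ov :], b[:ov], budget) <= budget:
            best = ov
    return best


def _containment_offset(a: str, b: str, min_identity: float) -> int | None:
    """Placement of b inside a within the substitution budget, or None."""
    if len(b) > len(a):
        return None
    budget = int((1.0 - min_identity) * len(b))
    w = max(4, min(_ANCHOR, len(b)))
    for off in (0, w, 2 * w):
        if off + w > len(b):
            break
        probe = b[off : off + w]
        start = 0
        while True:
            i = a.find(probe, start)
            if i < 0:
                break
            s = i - off
            if 0 <= s <= len(a) - len(b):
                if _mismatches(a[s : s + len(b)], b, budget) <= budget:
                    return s
            start = i + 1
    return None


def _pair_best(x: _Frag, y: _Frag, min_overlap: int, min_identity: float):
    """Best merge between two fragments.

    Same-orientation merges take precedence over reverse-complement ones;
    within an orientation, containment wins, then the longest overlap.
    Returns (overlap_or_span, kind, flip, extra) with kind in
    {'contain', 'xy', 'yx'}.
    """
    for flip in (False, True):
        best = None
        yseq = revcomp(y.seq) if flip else y.seq
        s = _containment_offset(x.seq, yseq, min_identity)
        if s is not None:
            best = (len(yseq), "contain", flip, s)
        else:
            ov = _best_overlap(x.seq, yseq, min_overlap, min_identity)
            if ov:
                best = (ov, "xy", flip, 0)
            ov2 = _best_overlap(yseq, x.seq, min_overlap, min_identity)
            if ov2 and (best is None or ov2 > best[0]):
                best = (ov2, "yx", flip, 0)
        if best is not None:
            return best
    return None


def _flip_members(members: list[_Member], frag_len: int,
                  read_len: dict[str, int]) -> list[_Member]:
    return [
        _Member(m.read_id, frag_len - m.offset - read_len[m.read_id], not m.rc)
        for m in members
    ]


def _shift(members: list[_Member], delta: int) -> list[_Member]:
    return [_Member(m.read_id, m.offset + delta, m.rc) for m in members]


def _polish(seq: str, members: list[_Member], read_seq: dict[str, str]) -> str:
    """Per-position majority vote over member reads; ties keep the layout base."""
    if len(members) <= 1:
        return seq
    counts: list[dict[str, int] | None] = [None] * len(seq)
    for m in members:
        bases = read_seq[m.read_id]
        if m.rc:
            bases = revcomp(bases)
        for i, b in enumerate(bases):
            p = m.offset + i
            if 0 <= p < len(seq):
                d = counts[p]
                if d is None:
                    d = counts[p] = {}
                d[b] = d.get(b, 0) + 1
    out = list(seq)
    for p, d in enumerate(counts):
        if not d:
            continue
        top = max(d.values())
        winners = sorted(b for b, n in d.items() if n == top)
        if len(winners) == 1 and winners[0] != out[p]:
            out[p] = winners[0]
        elif out[p] not in winners:
            out[p] = winners[0]
    return "".join(out)


def assemble(
    reads: Sequence[tuple[str, str]],
    min_overlap: int = 30,
    min_identity: float = 0.9,
    gene: str = "",
) -> list[Contig]:
    """Assemble (read_id, sequence) pairs into contigs for one gene bin.

    Greedy: the merge with the longest overlap wins each round, ties break on
    lexicographic fragment-id pairs. Deterministic for a fixed input set.
    """
    read_seq: dict[str, str] = {}
    read_len: dict[str, int] = {}
    frags: dict[str, _Frag] = {}
    for i, (rid, seq) in enumerate(sorted(reads)):
        seq = seq.upper()
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"read {rid} contains non-ACGTN characters")
        read_seq[rid] = seq
        read_len[rid] = len(seq)
        frags[f"f{i:06d}"] = _Frag(f"f{i:06d}", seq, [_Member(rid, 0, False)])

    cache: dict[tuple[str, str], tuple] = {}

    def compute(i: str, j: str) -> None:
        res = _pair_best(frags[i], frags[j], min_overlap, min_identity)
        if res is not None:
            cache[(i, j)] = res

    ids = sorted(frags)
    for ii, i in enumerate(ids):
        for j in ids[ii + 1 :]:
            compute(i, j)

    while cache:
        best_ov = max(v[0] for v in cache.values())
        i, j = min(k for k, v in cache.items() if v[0] == best_ov)
        ov, kind, flip, extra = cache[(i, j)]
        x, y = frags[i], frags[j]
        yseq = revcomp(y.seq) if flip else y.seq
        ymem = _flip_members(y.members, len(y.seq), read_len) if flip else y.members
        if kind == "contain":
            merged_seq = x.seq
            members = x.members + _shift(ymem, extra)
        elif kind == "xy":
            merged_seq = x.seq + yseq[ov:]
            members = x.members + _shift(ymem, len(x.seq) - ov)
        else:  # yx
            merged_seq = yseq + x.seq[ov:]
            members = ymem + _shift(x.members, len(yseq) - ov)
        merged = _Frag(min(i, j), merged_seq, members)
        for key in [k for k in cache if i in k or j in k]:
            del cache[key]
        del frags[i], frags[j]
        frags[merged.cid] = merged
        for other in sorted(frags):
            if other == merged.cid:
                continue
            a, b = sorted((merged.cid, other))
            compute(a, b)

    contigs = []
    order = sorted(frags, key=lambda c: (-len(frags[c].seq), c))
    for n, cid in enumerate(order):
        f = frags[cid]
        polished = _polish(f.seq, f.members, read_seq)
        contigs.append(
            Contig(f"{gene or 'bin'}_ctg{n + 1:03d}", gene, polished,
                   sorted(m.read_id for m in f.members))
        )
    return contigs
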