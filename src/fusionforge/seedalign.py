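"""Internal k-mer seeded alignment engine.

A lightweight substitute for an external short-read aligner at panel scale:
exact k-mer seeding against an indexed reference set, candidate shortlisting
by seed count, and alignment refinement with edlib (infix mode). Scoring for
best-hit selection follows short-read aligner conventions: match +1,
mismatch −4, gap open −6, gap extend −1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .models import revcomp

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -4, -6, -1

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def encode_seq(seq: str) -> np.ndarray:
    """Sequence to int8 codes (A=0..T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer value at every start position; −1 where any N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 4).all(axis=1)
    shifts = (2 * np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = (win.astype(np.int64) << shifts).sum(axis=1)
    return np.where(valid, vals, -1)


class KmerIndex:
    """Exact k-mer index over a set of named reference sequences."""

    def __init__(self, refs: Mapping[str, str], k: int = 17):
        self.k = k
        self.refs = dict(refs)
        self.names = sorted(self.refs)
        kmers_all = []
        names_all = []
        pos_all = []
        for ni, name in enumerate(self.names):
            codes = encode_seq(self.refs[name])
            km = kmer_codes(codes, k)
            keep = km >= 0
            kmers_all.append(km[keep])
            pos_all.append(np.nonzero(keep)[0])
            names_all.append(np.full(keep.sum(), ni, dtype=np.int32))
        if kmers_all:
            self._kmers = np.concatenate(kmers_all)
            self._pos = np.concatenate(pos_all).astype(np.int64)
            self._ref_idx = np.concatenate(names_all)
        else:
            self._kmers = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            self._ref_idx = np.empty(0, dtype=np.int32)
        order = np.argsort(self._kmers, kind="stable")
        self._kmers = self._kmers[order]
        self._pos = self._pos[order]
        self._ref_idx = self._ref_idx[order]

    def lookup(self, kmer_value: int) -> tuple[np.ndarray, np.ndarray]:
        """(ref indices, positions) of one k-mer value."""
        lo = np.searchsorted(self._kmers, kmer_value, "left")
        hi = np.searchsorted(self._kmers, kmer_value, "right")
        return self._ref_idx[lo:hi], self._pos[lo:hi]

    def seed_hits(self, query: str) -> dict[int, list[tuple[int, int]]]:
        """All exact seed matches: ref index -> [(query pos, ref pos), ...]."""
        km = kmer_codes(encode_seq(query), self.k)
        hits: dict[int, list[tuple[int, int]]] = {}
        valid = np.nonzero(km >= 0)[0]
        if len(valid) == 0:
            return hits
        vals = km[valid]
        lo = np.searchsorted(self._kmers, vals, "left")
        hi = np.searchsorted(self._kmers, vals, "right")
        for qpos, l, h in zip(valid, lo, hi):
            for j in range(l, h):
                hits.setdefault(int(self._ref_idx[j]), []).append(
                    (int(qpos), int(self._pos[j]))
                )
        return hits


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def score_cigar(cigar: str) -> tuple[int, int, int]:
    """(alignment score, aligned query length, edit count) from an edlib cigar."""
    score = 0
    qlen = 0
    edits = 0
    gap_state = None
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op in "=M":
            score += MATCH * n
            qlen += n
            gap_state = None
        elif op == "X":
            score += MISMATCH * n
            qlen += n
            edits += n
            gap_state = None
        else:  # I or D
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
            edits += n
            if op == "I":
                qlen += n
            gap_state = op
    return score, qlen, edits


@dataclass
class Hit:
    ref_name: str
    start: int          # 0-based half-open on the reference
    end: int
    strand: str
    score: int
    identity: float
    aligned_length: int


def align_query(
    query: str,
    index: KmerIndex,
    min_score: int = 30,
    max_candidates: int = 8,
) -> Hit | None:
    """Best local (infix) alignment of a read against the indexed references.

    Seeds shortlist candidate references; edlib refines each shortlisted
    (reference, strand) pair. Ties break toward the lexicographically
    smallest reference name, then the smallest start coordinate.
    """
    best: Hit | None = None
    for strand, seq in (("+", query), ("-", revcomp(query))):
        hits = index.seed_hits(seq)
        if not hits:
            continue
        ranked = sorted(hits, key=lambda ri: (-len(hits[ri]), ri))[:max_candidates]
        for ri in ranked:
            ref = index.refs[index.names[ri]]
            res = edlib.align(seq, ref, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            score, _, edits = score_cigar(res["cigar"])
            loc = min(res["locations"])
            alen = loc[1] + 1 - loc[0]
            identity = 1.0 - res["editDistance"] / max(alen, 1)
            hit = Hit(index.names[ri], loc[0], loc[1] + 1, strand, score,
                      identity, alen)
            if _better(hit, best):
                best = hit
    return best if best is not None and best.score >= min_score else None


def _better(a: Hit, b: Hit | None) -> bool:
    if b is None:
        return True
    return (-a.score, a.ref_name, a.start, a.strand) < (
        -b.score, b.ref_name, b.start, b.strand)
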