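"""Adapter trimming against an adapter FASTA (3'-end suffix matching).

The trimmer removes the longest read suffix that matches a prefix of any
adapter with at least ``min_overlap`` bases and a mismatch rate no greater
than ``max_mismatch_rate``; qualities are trimmed in lockstep. This mirrors
the default 3' adapter behaviour of read trimmers like fastp without the
binary dependency; an external engine can be substituted at the CLI level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io import FastqRecord, read_fasta


@dataclass
class AdapterSet:
    adapters: dict[str, str]
    min_overlap: int = 4
    max_mismatch_rate: float = 0.2

    def __post_init__(self) -> None:
        if not self.adapters:
            raise ValueError("adapter set is empty")
        for name, seq in self.adapters.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"adapter {name!r} must be non-empty uppercase ACGT")

    @classmethod
    def from_fasta(cls, path: str | Path, **kw) -> "AdapterSet":
        return cls(read_fasta(path), **kw)


def _suffix_overlap(read: str, adapter: str, min_overlap: int,
                    max_mismatch_rate: float) -> int:
    """Longest suffix of ``read`` matching a prefix of ``adapter``; 0 if none."""
    best = 0
    max_ov = min(len(read), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        budget = int(max_mismatch_rate * ov)
        mism = 0
        tail = read[len(read) - ov :]
        for a, b in zip(tail, adapter):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return ov
    return best


def trim_read(read: FastqRecord, adapters: AdapterSet) -> FastqRecord:
    """Remove adapter read-through from the 3' end of one read."""
    if not read.bases:
        return read
    best = 0
    for _, adapter in sorted(adapters.adapters.items()):
        ov = _suffix_overlap(read.bases, adapter, adapters.min_overlap,
                             adapters.max_mismatch_rate)
        best = max(best, ov)
    if best == 0:
        return read
    n = len(read.bases) - best
    return FastqRecord(read.read_id, read.bases[:n], read.quals[:n])


@dataclass
class TrimResult:
    r1: list[FastqRecord]
    r2: list[FastqRecord]
    dropped_pairs: int = 0
    kept_pairs: int = 0


def trim_pairs(
    r1: list[FastqRecord],
    r2: list[FastqRecord],
    adapters: AdapterSet | None,
    min_length: int = 30,
) -> TrimResult:
    """Trim both mates; drop pairs where either mate falls below ``min_length``.

    With no adapter set, only the length filter applies.
    """
    out1, out2, dropped = [], [], 0
    for a, b in zip(r1, r2):
        if adapters is not None:
            a, b = trim_read(a, adapters), trim_read(b, adapters)
        if len(a.bases) < min_length or len(b.bases) < min_length:
            dropped += 1
            continue
        out1.append(a)
        out2.append(b)
    return TrimResult(out1, out2, dropped_pairs=dropped, kept_pairs=len(out1))
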