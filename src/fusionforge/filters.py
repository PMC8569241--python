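"""False-positive filters: mononucleotide repeats, blocklist, single-transcript.

Each filter evaluates the unfiltered candidate and assigns a flag, so flag
assignment is order-independent; the kept set is exactly the candidates with
no dropping flags. The mononucleotide repeat ratio (MRR) of a window is the
length of its longest single-nucleotide run divided by the window length —
junctions flanked by homopolymers are classic assembly/alignment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .discovery import BreakpointCandidate

FLAG_MRR = "MRR"
FLAG_SHORT_WINDOW = "SHORT_WINDOW"
FLAG_BLOCKLIST = "BLOCKLIST"
FLAG_SINGLE_TX = "SINGLE_TX"
DROP_FLAGS = {FLAG_MRR, FLAG_BLOCKLIST, FLAG_SINGLE_TX}


@dataclass
class FilterConfig:
    mrr_window: int = 20
    mrr_threshold: float = 0.6
    blocklist_pairs: set[frozenset] = field(default_factory=set)
    blocklist_regions: list[tuple[str, int, int]] = field(default_factory=list)
    allowlist: dict[str, int] = field(default_factory=dict)  # gene -> min skipped exons

    def __post_init__(self) -> None:
        if not 0 < self.mrr_threshold <= 1:
            raise ValueError("mrr_threshold must be in (0, 1]")
        if self.mrr_window < 4:
            raise ValueError("mrr_window must be >= 4")


def load_blocklist(path: str | Path, config: FilterConfig) -> None:
    """TSV rows: either ``geneA<TAB>geneB`` or ``chrom<TAB>start<TAB>end``
    (1-based inclusive)."""
    for line in Path(path).read_text().splitlines():
        fields = line.strip().split("\t")
        if not line.strip() or line.startswith("#"):
            continue
        if len(fields) == 2:
            config.blocklist_pairs.add(frozenset(fields))
        elif len(fields) == 3:
            config.blocklist_regions.append((fields[0], int(fields[1]), int(fields[2])))
        else:
            raise ValueError(f"bad blocklist row: {line!r}")


def load_allowlist(path: str | Path, config: FilterConfig) -> None:
    """TSV rows: ``gene<TAB>min_skipped_exons`` (second column optional)."""
    for line in Path(path).read_text().splitlines():
        fields = line.strip().split("\t")
        if not line.strip() or line.startswith("#"):
            continue
        config.allowlist[fields[0]] = int(fields[1]) if len(fields) > 1 else 1


def mrr(sequence_window: str) -> float:
    """Longest single-nucleotide run length / window length, in (0, 1]."""
    if not sequence_window:
        raise ValueError("MRR of an empty window is undefined")
    longest = run = 1
    for a, b in zip(sequence_window, sequence_window[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest / len(sequence_window)


def junction_windows(candidate: BreakpointCandidate, window: int) -> tuple[str, str]:
    j = candidate.junction_offset
    seq = candidate.contig_sequence
    return seq[max(0, j - window) : j], seq[j : j + window]


def filter_mrr(candidate: BreakpointCandidate, config: FilterConfig) -> bool:
    """Flag-and-drop rule for homopolymeric junction flanks; True = keep."""
    left, right = junction_windows(candidate, config.mrr_window)
    if len(left) < 4 or len(right) < 4:
        candidate.filter_flags.add(FLAG_SHORT_WINDOW)
        return True
    if mrr(left) >= config.mrr_threshold or mrr(right) >= config.mrr_threshold:
        candidate.filter_flags.add(FLAG_MRR)
        return False
    return True


def _in_region(bp: tuple[str, int, str], region: tuple[str, int, int]) -> bool:
    chrom, start, end = region
    return bp[0] == chrom and start <= bp[1] <= end


def filter_blocklist(candidate: BreakpointCandidate, config: FilterConfig) -> bool:
    pair = frozenset((candidate.gene5, candidate.gene3))
    if pair in config.blocklist_pairs:
        candidate.filter_flags.add(FLAG_BLOCKLIST)
        return False
    for region in config.blocklist_regions:
        if _in_region(candidate.breakpoint5, region) or _in_region(
            candidate.breakpoint3, region
        ):
            candidate.filter_flags.add(FLAG_BLOCKLIST)
            return False
    return True


def filter_single_transcript(
    candidate: BreakpointCandidate, config: FilterConfig
) -> bool:
    """Drop same-gene events unless allowlisted with enough skipped exons.

    The skipped-exon count comes from the annotation (exon numbers on the
    two sides); a same-gene candidate qualifies when it skips at least the
    allowlist's per-gene minimum (EGFRvIII-class deletions).
    """
    if not candidate.gene5 or candidate.gene5 in ("", "NA"):
        return True
    if candidate.gene5 != candidate.gene3:
        return True
    min_skip = config.allowlist.get(candidate.gene5)
    if min_skip is not None and candidate.annotation is not None:
        ann = candidate.annotation
        if ann.exon5 is not None and ann.exon3 is not None:
            skipped = ann.exon3 - ann.exon5 - 1
            if skipped >= min_skip:
                return True
    candidate.filter_flags.add(FLAG_SINGLE_TX)
    return False


def apply_filters(
    candidates: Sequence[BreakpointCandidate],
    config: FilterConfig,
) -> tuple[list[BreakpointCandidate], list[BreakpointCandidate]]:
    """Evaluate every filter on every candidate; returns (kept, rejected)."""
    kept, rejected = [], []
    for cand in candidates:
        filter_mrr(cand, config)
        filter_blocklist(cand, config)
        filter_single_transcript(cand, config)
        if cand.filter_flags & DROP_FLAGS:
            rejected.append(cand)
        else:
            kept.append(cand)
    return kept, rejected
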