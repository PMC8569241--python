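"""Transcript models and small sequence utilities shared across the pipeline.

Coordinates follow the GTF convention: exons are 1-based, inclusive intervals
on the genome, stored sorted by genomic position. Transcription order is
genomic order on the plus strand and reversed on the minus strand, so exon 1
(E1) is always the 5'-most exon of the mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript: exon structure plus optional CDS on a genome.

    ``exons`` are (start, end) 1-based inclusive pairs sorted by genomic
    coordinate; ``cds_start``/``cds_end`` are genomic 1-based bounds of the
    coding region (None for non-coding transcripts such as NR_ accessions).
    """

    transcript_id: str
    gene: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")

    # -- structure ---------------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5' -> 3' along the mRNA."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def tx_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        """Number of coding bases (0 for non-coding transcripts)."""
        if self.cds_start is None:
            return 0
        n = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                n += hi - lo + 1
        return n

    # -- sequence ----------------------------------------------------------

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom = genome[self.chromosome]
        seq = "".join(chrom[s - 1 : e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    # -- coordinate mapping ------------------------------------------------

    def genomic_to_tx(self, pos: int) -> int | None:
        """Map a genomic 1-based exonic position to a 0-based mRNA offset.

        Returns None for intronic / out-of-span positions.
        """
        offset = 0
        for s, e in self.exons_tx_order():
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - pos)
            offset += e - s + 1
        return None

    def tx_to_genomic(self, offset: int) -> int:
        """Map a 0-based mRNA offset to its genomic 1-based position."""
        if offset < 0:
            raise IndexError("negative mRNA offset")
        for s, e in self.exons_tx_order():
            n = e - s + 1
            if offset < n:
                return s + offset if self.strand == "+" else e - offset
            offset -= n
        raise IndexError("mRNA offset beyond transcript length")

    def cds_start_tx(self) -> int | None:
        """0-based mRNA offset of the first coding base, or None."""
        if self.cds_start is None:
            return None
        gpos = self.cds_start if self.strand == "+" else self.cds_end
        return self.genomic_to_tx(gpos)

    def exon_number(self, exon_index_genomic: int) -> int:
        """1-based exon number in transcription order for a genomic index."""
        if self.strand == "+":
            return exon_index_genomic + 1
        return len(self.exons) - exon_index_genomic

    def exon_by_number(self, number: int) -> tuple[int, int]:
        """Exon interval for a 1-based transcription-order exon number."""
        if not 1 <= number <= len(self.exons):
            raise IndexError(f"exon E{number} out of range for {self.transcript_id}")
        return self.exons_tx_order()[number - 1]

    def exon_tx_end_position(self, number: int) -> tuple[str, int, str]:
        """Genomic breakpoint at the transcription-order END of exon ``number``."""
        s, e = self.exon_by_number(number)
        pos = e if self.strand == "+" else s
        return self.chromosome, pos, self.strand

    def exon_tx_start_position(self, number: int) -> tuple[str, int, str]:
        """Genomic breakpoint at the transcription-order START of exon ``number``."""
        s, e = self.exon_by_number(number)
        pos = s if self.strand == "+" else e
        return self.chromosome, pos, self.strand


@dataclass
class SyntheticPanel:
    """A synthetic targeted gene panel: genome plus one transcript per gene."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_names:
            self.gene_names = [t.gene for t in self.transcripts]

    def transcript_for(self, gene: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.gene == gene:
                return t
        raise KeyError(f"unknown gene {gene!r}")
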