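"""File IO helpers: FASTQ/FASTA records, GTF and truth-table writers.

pysam handles reading (plain, gzip and BGZF transparently); writers emit
plain text or gzip depending on the filename suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

from .models import SyntheticPanel, TranscriptModel

PHRED_OFFSET = 33


@dataclass
class FastqRecord:
    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"bases/quals length mismatch for {self.read_id}")

    @property
    def qual_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.quals)

    def to_fastq(self) -> str:
        return f"@{self.read_id}\n{self.bases}\n+\n{self.qual_string}\n"


def _opener(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t") if "b" not in mode else gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            quals = entry.get_quality_array()
            yield FastqRecord(entry.name, entry.sequence.upper(), list(quals))


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with _opener(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_fastq())


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence.upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome(panel: SyntheticPanel, fasta_path: str | Path) -> None:
    """Write the panel genome as FASTA and index it (.fai)."""
    write_fasta(panel.genome, fasta_path)
    pysam.faidx(str(fasta_path))


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as a minimal exon/CDS GTF."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_name "{t.gene}"; transcript_id "{t.transcript_id}"; '
                f'canonical "{1 if t.canonical else 0}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chromosome}\tfusionforge\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_start is not None:
                for s, e in t.exons:
                    lo, hi = max(s, t.cds_start), min(e, t.cds_end)
                    if lo <= hi:
                        fh.write(
                            f"{t.chromosome}\tfusionforge\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from a GTF with exon and CDS features."""
    import pyranges

    df = pyranges.read_gtf(str(path)).df
    models: list[TranscriptModel] = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        exon_rows = sub[sub.Feature == "exon"]
        cds_rows = sub[sub.Feature == "CDS"]
        # pyranges converts to 0-based half-open; convert back to GTF 1-based inclusive
        exons = sorted((int(r.Start) + 1, int(r.End)) for r in exon_rows.itertuples())
        cds_start = cds_end = None
        if len(cds_rows):
            cds_start = int(cds_rows.Start.min()) + 1
            cds_end = int(cds_rows.End.max())
        first = exon_rows.iloc[0]
        canonical = True
        if "canonical" in exon_rows.columns:
            canonical = str(first.get("canonical", "1")) in ("1", "True", "true")
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene=str(first.gene_name),
                chromosome=str(first.Chromosome),
                strand=str(first.Strand),
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                canonical=canonical,
            )
        )
    return models
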