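"""Gene-level read binning and identical-coordinate read reduction.

Consensus reads are aligned to a gene reference (the longest coding
transcript per gene), binned by best-hit gene, and each bin is thinned so
that at most ``max_copies`` reads share an identical (aligned length, start,
end) coordinate signature before de novo assembly. Reads that align nowhere
are kept in an "unassigned" pool that still reaches confirmation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import FastqRecord
from .models import SyntheticPanel, TranscriptModel
from .seedalign import Hit, KmerIndex, align_query


@dataclass
class GeneReference:
    sequences: dict[str, str]          # gene -> transcript sequence
    provenance: dict[str, str]         # gene -> transcript id

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.provenance):
            raise ValueError("sequences/provenance out of sync")


@dataclass
class ReadAlignment:
    read_id: str
    gene: str
    start: int
    end: int
    strand: str
    score: int
    aligned_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad alignment interval for {self.read_id}")

    @property
    def signature(self) -> tuple[int, int, int]:
        return (self.aligned_length, self.start, self.end)


def build_gene_reference(
    transcript_models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> GeneReference:
    """Pick one transcript per gene: maximal CDS length, ties broken by total
    length then lexicographic transcript id; genes with no coding transcript
    fall back (with a warning) to the longest transcript."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcript_models:
        by_gene.setdefault(t.gene, []).append(t)
    seqs: dict[str, str] = {}
    prov: dict[str, str] = {}
    for gene, txs in sorted(by_gene.items()):
        coding = [t for t in txs if t.cds_start is not None]
        pool = coding
        if not coding:
            warnings.warn(f"gene {gene} has no coding transcript; using longest")
            pool = txs
        best = min(pool, key=lambda t: (-t.cds_length, -t.tx_length, t.transcript_id))
        seqs[gene] = best.spliced_sequence(genome)
        prov[gene] = best.transcript_id
    return GeneReference(seqs, prov)


def gene_reference_from_panel(panel: SyntheticPanel) -> GeneReference:
    return build_gene_reference(panel.transcripts, panel.genome)


@dataclass
class BinningResult:
    alignments: dict[str, ReadAlignment]            # read_id -> best hit
    bins: dict[str, list[str]]                      # gene -> read ids (pairs merged)
    unassigned: list[str] = field(default_factory=list)


def align_to_genes(
    reads: Sequence[FastqRecord],
    reference: GeneReference,
    k: int = 17,
    min_score: int = 30,
    index: KmerIndex | None = None,
) -> tuple[dict[str, ReadAlignment], list[str]]:
    """Single best-scoring gene alignment per read; None -> unassigned pool."""
    if not reference.sequences:
        raise ValueError("empty gene reference")
    idx = index or KmerIndex(reference.sequences, k=k)
    alignments: dict[str, ReadAlignment] = {}
    unassigned: list[str] = []
    for rec in reads:
        hit: Hit | None = align_query(rec.bases, idx, min_score=min_score)
        if hit is None:
            unassigned.append(rec.read_id)
        else:
            alignments[rec.read_id] = ReadAlignment(
                rec.read_id, hit.ref_name, hit.start, hit.end, hit.strand,
                hit.score, hit.aligned_length,
            )
    return alignments, unassigned


def bin_pairs(
    r1: Sequence[FastqRecord],
    r2: Sequence[FastqRecord],
    reference: GeneReference,
    k: int = 17,
    min_score: int = 30,
) -> BinningResult:
    """Bin read pairs by the better-scoring mate; both mates enter the bin."""
    idx = KmerIndex(reference.sequences, k=k)
    a1, u1 = align_to_genes(r1, reference, k=k, min_score=min_score, index=idx)
    suffixed_r2 = [FastqRecord(rec.read_id + "/2", rec.bases, rec.quals) for rec in r2]
    a2, u2 = align_to_genes(suffixed_r2, reference, k=k, min_score=min_score, index=idx)

    alignments = dict(a1)
    alignments.update(a2)
    bins: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for rec1, rec2 in zip(r1, r2):
        h1 = a1.get(rec1.read_id)
        h2 = a2.get(rec1.read_id + "/2")
        if h1 is None and h2 is None:
            unassigned.extend([rec1.read_id, rec1.read_id + "/2"])
            continue
        if h2 is None or (h1 is not None and (-h1.score, h1.gene) <= (-h2.score, h2.gene)):
            gene = h1.gene
        else:
            gene = h2.gene
        bins.setdefault(gene, []).extend([rec1.read_id, rec1.read_id + "/2"])
    return BinningResult(alignments, bins, unassigned)


def reduce_bin(
    bin_alignments: Sequence[ReadAlignment],
    max_copies: int = 5,
) -> list[ReadAlignment]:
    """Cap identical-coordinate alignment groups at ``max_copies`` reads.

    Groups share (aligned length, start, end); kept reads are the first
    ``max_copies`` by read-id sort, so reduction is deterministic and never
    removes the last copy of a group.
    """
    groups: dict[tuple[int, int, int], list[ReadAlignment]] = {}
    for a in bin_alignments:
        groups.setdefault(a.signature, []).append(a)
    kept: list[ReadAlignment] = []
    for sig in sorted(groups):
        members = sorted(groups[sig], key=lambda a: a.read_id)
        kept.extend(members[:max_copies])
    return kept


def reduce_bins(
    result: BinningResult,
    max_copies: int = 5,
) -> dict[str, list[str]]:
    """Apply per-gene reduction; returns gene -> retained read ids."""
    out: dict[str, list[str]] = {}
    for gene in sorted(result.bins):
        ids = result.bins[gene]
        aligned = [result.alignments[r] for r in ids if r in result.alignments]
        unaligned_ids = [r for r in ids if r not in result.alignments]
        kept = reduce_bin(aligned, max_copies=max_copies)
        out[gene] = sorted([a.read_id for a in kept] + unaligned_ids)
    return out
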