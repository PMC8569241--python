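"""Synthetic panel, fusion truth sets, and UMI-tagged amplicon read simulation.

The generator emulates a targeted RNA fusion panel with QIAseq-style
chemistry: each cDNA molecule receives a unique molecular index (UMI) before
PCR, amplified copies share the UMI and differ only by substitution
sequencing errors, and paired reads cover the two ends of a short fragment.
Every downstream stage of the pipeline can therefore be exercised against a
known truth table without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FastqRecord, write_fastq, write_genome, write_gtf
from .models import SyntheticPanel, TranscriptModel, revcomp

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _ACGT[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class SimConfig:
    """Knobs of the read simulator; the seed fully determines the output."""

    seed: int = 0
    umi_length: int = 12
    umi_read: str = "R1"
    read_length: int = 100
    error_rate: float = 0.01
    duplicate_rate: float = 3.0
    n_background_molecules: int = 600
    fragment_min: int = 110
    fragment_max: int = 150

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.umi_length > 16:
            raise ValueError("umi_length must be <= 16 (2-bit k-mer encoding limit)")
        if self.umi_read not in ("R1", "R2"):
            raise ValueError("umi_read must be 'R1' or 'R2'")
        if self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be >= 1")
        if self.read_length <= self.umi_length + 20:
            raise ValueError("read_length too short for the UMI plus an insert")


@dataclass
class FusionTruth:
    """A planted fusion event with exact genomic breakpoints."""

    fusion_id: str
    gene5: str
    gene3: str
    breakpoint5: tuple[str, int, str]
    breakpoint3: tuple[str, int, str]
    junction_sequence: str
    junction_offset: int  # 0-based index of the first 3'-side base
    n_molecules: int = 50
    planted_read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def make_panel(n_genes: int, seed: int) -> SyntheticPanel:
    """Build a synthetic multi-exon gene panel on a synthetic genome.

    One gene per chromosome, each with a single canonical coding transcript
    of 3-6 exons (170-400 bp) separated by 3-9 kb introns. Exon sizes keep
    150 bp confirmation flanks exonic; intron sizes keep single-splice
    contigs below the fusion-scale genomic-gap threshold.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes to plant an inter-gene fusion")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    for g in range(n_genes):
        gene = f"GENE{g + 1:03d}"
        chrom = f"chr{g + 1}"
        n_exons = int(rng.integers(3, 7))
        exon_lens = rng.integers(170, 401, n_exons)
        intron_lens = rng.integers(3000, 9001, n_exons - 1)
        pad = 2000
        pos = pad + 1
        exons = []
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        chrom_len = pos - 1 + pad
        genome[chrom] = _random_seq(rng, chrom_len)
        strand = "+" if rng.random() < 0.5 else "-"
        tx = TranscriptModel(
            transcript_id=f"TX_{gene}",
            gene=gene,
            chromosome=chrom,
            strand=strand,
            exons=exons,
        )
        # CDS in transcript space: starts/ends inside the terminal exons,
        # length forced to a whole number of codons
        tx_len = tx.tx_length
        cds_start_tx = int(rng.integers(9, 100))
        cds_end_tx = tx_len - int(rng.integers(9, 100))
        cds_len = cds_end_tx - cds_start_tx
        cds_end_tx = cds_start_tx + cds_len - (cds_len % 3)
        g1 = tx.tx_to_genomic(cds_start_tx)
        g2 = tx.tx_to_genomic(cds_end_tx - 1)
        tx.cds_start, tx.cds_end = min(g1, g2), max(g1, g2)
        transcripts.append(tx)
    return SyntheticPanel(genome=genome, transcripts=transcripts)


def plant_fusion(
    panel: SyntheticPanel,
    gene5: str,
    gene3: str,
    exon5_index: int,
    exon3_index: int,
    n_molecules: int = 50,
) -> FusionTruth:
    """Join the end of exon ``exon5_index`` of gene5 to the start of exon
    ``exon3_index`` of gene3 (1-based, transcription order).

    With gene5 == gene3 and exon5_index < exon3_index - 1 this produces an
    intragenic exon-skipping deletion (EGFRvIII-like).
    """
    t5 = panel.transcript_for(gene5)
    t3 = panel.transcript_for(gene3)
    bp5 = t5.exon_tx_end_position(exon5_index)
    bp3 = t3.exon_tx_start_position(exon3_index)
    seq5 = t5.spliced_sequence(panel.genome)
    seq3 = t3.spliced_sequence(panel.genome)
    keep5 = sum(e - s + 1 for s, e in t5.exons_tx_order()[:exon5_index])
    skip3 = sum(e - s + 1 for s, e in t3.exons_tx_order()[: exon3_index - 1])
    part5 = seq5[:keep5]
    part3 = seq3[skip3:]
    return FusionTruth(
        fusion_id=f"{gene5}-{gene3}-E{exon5_index}E{exon3_index}",
        gene5=gene5,
        gene3=gene3,
        breakpoint5=bp5,
        breakpoint3=bp3,
        junction_sequence=part5 + part3,
        junction_offset=len(part5),
        n_molecules=n_molecules,
    )


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _ACGT[_ACGT != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _quals(rng: np.random.Generator, n: int) -> list[int]:
    return [int(q) for q in rng.integers(30, 41, n)]


def simulate_reads(
    panel: SyntheticPanel,
    truths: list[FusionTruth],
    config: SimConfig,
) -> tuple[list[FastqRecord], list[FastqRecord], pd.DataFrame]:
    """Simulate UMI-tagged paired reads for planted fusions plus background.

    Each molecule is a short fragment of a (fused or normal) mRNA; fusion
    fragments always span the junction by >= 25 bases on both sides, and the
    first fragment of every truth is centred so one read overlaps the
    junction by at least a third of the read length. Returns R1/R2 records
    and a molecule truth table; ``truth.planted_read_ids`` is filled in.
    """
    rng = np.random.default_rng(config.seed)
    insert_len = config.read_length - config.umi_length
    used_umis: set[str] = set()

    def fresh_umi() -> str:
        while True:
            u = _random_seq(rng, config.umi_length)
            if u not in used_umis:
                used_umis.add(u)
                return u

    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    rows: list[dict] = []
    mol_counter = 0

    def emit_molecule(template: str, start: int, frag_len: int, origin: str,
                      truth: FusionTruth | None) -> None:
        nonlocal mol_counter
        frag = template[start : start + frag_len]
        umi = fresh_umi()
        mol_id = f"M{mol_counter:06d}|{origin}"
        mol_counter += 1
        n_copies = 1 + int(rng.poisson(config.duplicate_rate - 1.0))
        ins1 = frag[:insert_len]
        ins2 = revcomp(frag[-config.read_length :])
        for c in range(n_copies):
            rid = f"{mol_id}|c{c}"
            if config.umi_read == "R1":
                b1 = _mutate(rng, umi + ins1, config.error_rate)
                b2 = _mutate(rng, ins2, config.error_rate)
            else:
                b1 = _mutate(rng, ins1, config.error_rate)
                b2 = _mutate(rng, umi + ins2, config.error_rate)
            r1.append(FastqRecord(rid, b1, _quals(rng, len(b1))))
            r2.append(FastqRecord(rid, b2, _quals(rng, len(b2))))
            if truth is not None:
                truth.planted_read_ids.append(rid)
        rows.append(
            {"molecule_id": mol_id, "origin": origin, "umi": umi,
             "fragment_start": start, "fragment_length": frag_len,
             "n_copies": n_copies}
        )

    for truth in truths:
        template = truth.junction_sequence
        j0 = truth.junction_offset
        for m in range(truth.n_molecules):
            frag_len = int(rng.integers(config.fragment_min, config.fragment_max + 1))
            if m == 0:
                d = min(frag_len - 25, max(25, insert_len // 2))
            else:
                d = int(rng.integers(25, frag_len - 24))
            start = max(0, min(j0 - d, len(template) - frag_len))
            emit_molecule(template, start, frag_len, truth.fusion_id, truth)

    spliced = {t.gene: t.spliced_sequence(panel.genome) for t in panel.transcripts}
    genes = sorted(spliced)
    for _ in range(config.n_background_molecules):
        gene = genes[int(rng.integers(0, len(genes)))]
        template = spliced[gene]
        frag_len = int(rng.integers(config.fragment_min, config.fragment_max + 1))
        frag_len = min(frag_len, len(template))
        start = int(rng.integers(0, len(template) - frag_len + 1))
        emit_molecule(template, start, frag_len, f"BG:{gene}", None)

    return r1, r2, pd.DataFrame(rows)


def truth_table(truths: list[FusionTruth]) -> pd.DataFrame:
    """Tabulate planted fusions in the on-disk truth TSV layout."""
    rows = []
    for t in truths:
        c5, p5, s5 = t.breakpoint5
        c3, p3, s3 = t.breakpoint3
        rows.append(
            {"fusion_id": t.fusion_id, "gene5": t.gene5, "gene3": t.gene3,
             "chrom5": c5, "pos5": p5, "strand5": s5,
             "chrom3": c3, "pos3": p3, "strand3": s3,
             "n_molecules": t.n_molecules}
        )
    return pd.DataFrame(
        rows,
        columns=["fusion_id", "gene5", "gene3", "chrom5", "pos5", "strand5",
                 "chrom3", "pos3", "strand3", "n_molecules"],
    )


def write_simulation(
    panel: SyntheticPanel,
    truths: list[FusionTruth],
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Run the simulator and write genome FASTA(+fai), GTF, FASTQs and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r1, r2, molecules = simulate_reads(panel, truths, config)
    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "panel.gtf",
        "r1": out / "reads_R1.fastq.gz",
        "r2": out / "reads_R2.fastq.gz",
        "truth": out / "truth.tsv",
        "molecules": out / "molecules.tsv",
    }
    write_genome(panel, paths["genome"])
    write_gtf(panel.transcripts, paths["gtf"])
    write_fastq(r1, paths["r1"])
    write_fastq(r2, paths["r2"])
    truth_table(truths).to_csv(paths["truth"], sep="\t", index=False)
    molecules.to_csv(paths["molecules"], sep="\t", index=False)
    return paths


def default_fusion_set(panel: SyntheticPanel, n_fusions: int, seed: int,
                       n_molecules: int = 50) -> list[FusionTruth]:
    """Plant ``n_fusions`` distinct inter-gene fusions across the panel.

    Gene pairs are drawn without replacement; junction exons are interior
    boundaries so both sides carry assembled flank.
    """
    rng = np.random.default_rng(seed)
    genes = list(panel.gene_names)
    pairs: list[tuple[str, str]] = []
    seen = set()
    guard = 0
    while len(pairs) < n_fusions:
        guard += 1
        if guard > 100 * n_fusions:
            raise ValueError("cannot find enough distinct gene pairs")
        i, j = rng.integers(0, len(genes), 2)
        if i == j:
            continue
        pair = (genes[int(i)], genes[int(j)])
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    truths = []
    for k, (g5, g3) in enumerate(pairs):
        t5 = panel.transcript_for(g5)
        t3 = panel.transcript_for(g3)
        e5 = int(rng.integers(1, t5.n_exons))          # not the last exon
        e3 = int(rng.integers(2, t3.n_exons + 1))      # not the first exon
        truths.append(plant_fusion(panel, g5, g3, e5, e3, n_molecules=n_molecules))
    return truths
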