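"""End-to-end orchestration: dedupe → trim → bin → assemble → discover →
filter → annotate → confirm, with per-gene parallel assembly and
deterministic, thread-count-invariant outputs."""

from __future__ import annotations

import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import annotation as ann_mod
from . import confirm as confirm_mod
from .assembly import Contig, assemble
from .binning import bin_pairs, build_gene_reference, reduce_bins
from .dedup import DedupConfig, dedupe_records
from .discovery import (BreakpointCandidate, GenomeIndex, call_candidates,
                        collapse_redundant, split_align)
from .filters import FilterConfig, apply_filters
from .io import FastqRecord, read_fasta, read_fastq, read_gtf
from .models import TranscriptModel
from .trim import AdapterSet, trim_pairs


@dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults."""

    # dedupe
    umi_length: int = 12
    umi_read: str = "R1"
    max_hamming: int = 1
    qual_cap: int = 60
    # trim
    min_read_length: int = 30
    # binning
    bin_k: int = 17
    min_align_score: int = 30
    max_copies: int = 5
    # assembly
    min_overlap: int = 30
    min_assembly_identity: float = 0.9
    # discovery
    genome_k: int = 17
    min_segment: int = 25
    min_segment_identity: float = 0.9
    min_genomic_gap: int = 10000
    merge_window: int = 5
    # filters
    mrr_window: int = 20
    mrr_threshold: float = 0.6
    # annotation
    boundary_tolerance: int = 3
    # confirmation
    flank: int = 150
    min_span: int = 10
    min_support: int = 1
    min_support_identity: float = 0.9
    # execution
    threads: int = 1

    def to_file(self, path: str | Path) -> None:
        import configparser

        cp = configparser.ConfigParser()
        cp["fusionforge"] = {k: str(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import configparser

        cp = configparser.ConfigParser()
        cp.read(path)
        section = cp["fusionforge"]
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in section:
                kwargs[f_.name] = type(f_.default)(section[f_.name])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    calls: list
    candidates: list[BreakpointCandidate]
    rejected: list[BreakpointCandidate]
    contigs: list[Contig]
    vcf_text: str
    manifest: dict
    dedup_r1: list[FastqRecord] = field(default_factory=list)
    dedup_r2: list[FastqRecord] = field(default_factory=list)


def _assemble_gene(args):
    gene, reads, min_overlap, min_identity = args
    return gene, assemble(reads, min_overlap=min_overlap,
                          min_identity=min_identity, gene=gene)


def run_pipeline(
    r1: Sequence[FastqRecord],
    r2: Sequence[FastqRecord],
    genome: Mapping[str, str],
    transcript_models: Sequence[TranscriptModel],
    config: PipelineConfig | None = None,
    adapters: AdapterSet | None = None,
    filter_config: FilterConfig | None = None,
) -> PipelineResult:
    """Run the whole workflow in memory; deterministic for fixed inputs."""
    cfg = config or PipelineConfig()
    fcfg = filter_config or FilterConfig(
        mrr_window=cfg.mrr_window, mrr_threshold=cfg.mrr_threshold
    )
    manifest: dict = {"parameters": asdict(cfg), "stages": {}}

    # 1. UMI consensus dedupe
    dd = dedupe_records(
        list(r1), list(r2),
        DedupConfig(umi_length=cfg.umi_length, umi_read=cfg.umi_read,
                    max_hamming=cfg.max_hamming, qual_cap=cfg.qual_cap),
    )
    manifest["stages"]["dedupe"] = dd.stats

    # strip the UMI from the tagged mate for all downstream analysis
    def _template(rec: FastqRecord, tagged: bool) -> FastqRecord:
        if not tagged:
            return rec
        n = cfg.umi_length
        return FastqRecord(rec.read_id, rec.bases[n:], rec.quals[n:])

    t1 = [_template(rec, cfg.umi_read == "R1") for rec in dd.r1]
    t2 = [_template(rec, cfg.umi_read == "R2") for rec in dd.r2]

    # 2. adapter trim + length filter
    tr = trim_pairs(t1, t2, adapters, min_length=cfg.min_read_length)
    manifest["stages"]["trim"] = {
        "input_pairs": len(t1), "kept_pairs": tr.kept_pairs,
        "dropped_pairs": tr.dropped_pairs,
    }

    # 3. gene binning + identical-coordinate reduction
    reference = build_gene_reference(transcript_models, genome)
    binning = bin_pairs(tr.r1, tr.r2, reference, k=cfg.bin_k,
                        min_score=cfg.min_align_score)
    reduced = reduce_bins(binning, max_copies=cfg.max_copies)
    manifest["stages"]["binning"] = {
        "aligned_reads": len(binning.alignments),
        "unassigned_reads": len(binning.unassigned),
        "genes_with_reads": len(reduced),
        "reads_after_reduction": sum(len(v) for v in reduced.values()),
    }

    seq_of = {rec.read_id: rec.bases for rec in tr.r1}
    seq_of.update({rec.read_id + "/2": rec.bases for rec in tr.r2})

    # 4. per-gene de novo assembly (parallel unit = gene bin; merge sorted)
    tasks = [
        (gene, [(rid, seq_of[rid]) for rid in sorted(reduced[gene])],
         cfg.min_overlap, cfg.min_assembly_identity)
        for gene in sorted(reduced)
    ]
    contigs: list[Contig] = []
    if cfg.threads > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=cfg.threads) as ex:
            results = dict(ex.map(_assemble_gene, tasks))
    else:
        results = dict(map(_assemble_gene, tasks))
    for gene in sorted(results):
        contigs.extend(results[gene])
    manifest["stages"]["assembly"] = {"contigs": len(contigs)}

    # 5. split alignment + breakpoint candidates
    gindex = GenomeIndex(genome, k=cfg.genome_k)
    raw: list[BreakpointCandidate] = []
    for contig in contigs:
        segs = split_align(contig, genome, gindex,
                           min_segment=cfg.min_segment,
                           min_identity=cfg.min_segment_identity)
        raw.extend(call_candidates(contig, segs,
                                   min_genomic_gap=cfg.min_genomic_gap))
    raw = [ann_mod.orient_candidate(c, transcript_models,
                                    tolerance=cfg.boundary_tolerance)
           for c in raw]
    candidates = collapse_redundant(raw, merge_window=cfg.merge_window)
    manifest["stages"]["discovery"] = {
        "raw_candidates": len(raw), "collapsed_candidates": len(candidates),
    }

    # 6. annotation, then filters
    for cand in candidates:
        ann_mod.annotate(cand, transcript_models, tolerance=cfg.boundary_tolerance)
    kept, rejected = apply_filters(candidates, fcfg)
    manifest["stages"]["filters"] = {
        "input": len(candidates), "kept": len(kept), "rejected": len(rejected),
    }

    # 7. confirmation against chimeric constructs
    reads = [FastqRecord(r.read_id + "/1", r.bases, r.quals) for r in tr.r1]
    reads += [FastqRecord(r.read_id + "/2", r.bases, r.quals) for r in tr.r2]
    transcriptome = reference.sequences
    calls = confirm_mod.confirm_candidates(
        kept, genome, reads, transcriptome,
        flank=cfg.flank, min_span=cfg.min_span, min_support=cfg.min_support,
        min_identity=cfg.min_support_identity,
        allowlist_genes=set(fcfg.allowlist),
    )
    manifest["stages"]["confirmation"] = {
        "candidates": len(kept), "calls": len(calls),
    }
    vcf_text = confirm_mod.emit_vcf(calls, genome, mrr_window=cfg.mrr_window)
    return PipelineResult(calls, kept, rejected, contigs, vcf_text, manifest,
                          dd.r1, dd.r2)


def candidate_table(candidates: Sequence[BreakpointCandidate]):
    import pandas as pd

    rows = []
    for c in candidates:
        ann = c.annotation
        rows.append(
            {
                "contig_id": c.contig_id,
                "chrom5": c.breakpoint5[0], "pos5": c.breakpoint5[1],
                "strand5": c.breakpoint5[2],
                "chrom3": c.breakpoint3[0], "pos3": c.breakpoint3[1],
                "strand3": c.breakpoint3[2],
                "gene5": c.gene5, "gene3": c.gene3,
                "location": ann.location_class if ann else "",
                "frame": ann.frame_status if ann else "",
                "label5": ann.label5 if ann else "",
                "label3": ann.label3 if ann else "",
                "flags": ",".join(sorted(c.filter_flags)),
                "supporting_reads": c.supporting_read_count,
            }
        )
    return pd.DataFrame(rows)


def run(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    genome_fasta: str | Path,
    gtf: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    adapters_fasta: str | Path | None = None,
    blocklist: str | Path | None = None,
    allowlist: str | Path | None = None,
) -> PipelineResult:
    """File-level pipeline entry point; writes VCF, tables, IGV session, manifest."""
    from .filters import load_allowlist, load_blocklist
    from .io import write_fastq

    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_fasta)
    models = read_gtf(gtf)
    adapters = AdapterSet.from_fasta(adapters_fasta) if adapters_fasta else None
    fcfg = FilterConfig(mrr_window=cfg.mrr_window, mrr_threshold=cfg.mrr_threshold)
    if blocklist:
        load_blocklist(blocklist, fcfg)
    if allowlist:
        load_allowlist(allowlist, fcfg)

    r1 = list(read_fastq(fastq_r1))
    r2 = list(read_fastq(fastq_r2))
    result = run_pipeline(r1, r2, genome, models, cfg, adapters, fcfg)

    (out / "calls.vcf").write_text(result.vcf_text)
    write_fastq(result.dedup_r1, out / "dedup_R1.fastq.gz")
    write_fastq(result.dedup_r2, out / "dedup_R2.fastq.gz")
    candidate_table(result.candidates).to_csv(out / "candidates.tsv", sep="\t",
                                              index=False)
    candidate_table(result.rejected).to_csv(out / "rejected.tsv", sep="\t",
                                            index=False)
    confirm_mod.igv_session(result.calls, out)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result
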