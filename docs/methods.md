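# Methods

This note documents the models, defaults and design choices behind
`fusionforge`, and what the synthetic-data tests do and do not demonstrate.

## UMI consensus model

Reads sharing a unique molecular index (UMI) are PCR copies of one molecule;
sequencing errors make the copies differ, both in the template and in the
UMI itself. Clustering is greedy and count-descending: the most frequent
exact UMI seeds a cluster and absorbs all UMIs within `max_hamming`
(default 1, the standard single-error tolerance for 12-mers). Seeds are
ordered by (count desc, 2-bit-encoded UMI asc), which makes clustering fully
deterministic; by construction surviving representatives are pairwise more
than `max_hamming` apart, so deduplication is idempotent. UMIs containing N
are left as singleton clusters rather than guessed.

Per position, the consensus assumes conditionally independent observations
with the usual Phred error model: an observed base equals the true base with
probability 1 − e and is otherwise one of the three alternatives uniformly
(e/3). With a uniform prior over {A,C,G,T} the posterior is a product over
cluster members; the consensus base is the maximum-posterior base with exact
ties broken lexicographically, and the output quality is the phred-scaled
posterior error, capped at `qual_cap = 60` to avoid runaway scores while
still exceeding the instrument range. A single observation of quality Q
reproduces Q exactly, which is why single-read clusters pass through
unchanged. Base qualities are floored at e ≤ 0.75 so Q0 inputs stay finite.
Cluster members may differ in length after trimming; the consensus length is
the modal member length and shorter members vote only on positions they
cover. The consensus R1 keeps the read structure of its inputs — the
representative UMI is written back into the UMI slice — so the deduper can
be re-run on its own output (a no-op), and downstream stages strip the UMI
explicitly.

The exact update used by the original C implementation is not public; the
model above is the canonical conditional-independence formulation consistent
with its description, and the brute-force oracle tests pin this package to
that definition.

## Alignment engines

All three alignment tasks use one internal engine family rather than
external binaries, so the pipeline is self-contained and deterministic at
panel scale:

- **Read-to-gene binning**: exact 17-mer seeds shortlist candidate
  transcripts; edlib (infix mode) refines each candidate; hits are scored
  match +1 / mismatch −4 / gap open −6 / gap extend −1 and the single best
  hit wins (ties → lexicographically smaller gene, then smaller start).
  Reads scoring below 30 go to an "unassigned" pool that still reaches
  confirmation. Pairs are binned by the better-scoring mate and coordinate
  groups are interpreted on the transcript the reads were aligned to.
- **Contig-to-genome split alignment**: exact 17-mer seeds grouped by
  (chromosome, diagonal), runs split when consecutive seeds are > 50 bp
  apart, then extended with x-drop (match +1, mismatch −3, drop 8). Segments
  shorter than 25 bp or below 90% identity are discarded. The engine is
  substitution-oriented by design, matching the simulator's error model;
  indel-containing contigs would fragment into shorter segments.
- **Read-to-construct support counting**: edlib infix alignment in both
  orientations with a 90% identity guard across the alignment.

## Assembly

The per-gene assembler is a greedy overlap-layout-consensus procedure:
repeatedly merge the fragment pair with the longest suffix–prefix overlap
≥ 30 bp at ≥ 90% identity, preferring same-orientation merges over
reverse-complement ones and containments over dovetails, with lexicographic
tie-breaking for determinism. Candidate overlaps are proposed by short exact
anchors from the incoming fragment's prefix (the anchor shrinks to the
minimum overlap when that is smaller), which is reliable under a
substitution-only error model. After layout, each contig is polished by
per-position majority vote over its member reads; this removes isolated
errors that survive UMI consensus in low-duplicate clusters and measurably
sharpens breakpoint placement. Singleton reads are emitted as contigs so a
single junction-spanning molecule can still nominate a breakpoint.

## Breakpoint calling conventions

A candidate requires two segments that tile the contig (gap and overlap
each ≤ 10 bp) and are genomically non-contiguous: different chromosomes, a
strand change, or a same-strand gap > `min_genomic_gap` = 10 kb. The 10 kb
threshold separates fusion-scale events from intron-scale splicing;
intragenic deletions that skip enough sequence (EGFRvIII-class) exceed it
and re-enter via the allowlist. When the two segments overlap on the contig
the junction is micro-homologous and inherently ambiguous; the junction is
placed mid-overlap, bounding the reported-breakpoint error by half the
homology length. Contig orientation is arbitrary, so every candidate is
re-oriented to transcript sense (flip when the alignment strands disagree
with the gene strands on both sides) before redundancy collapsing, which
merges breakpoint pairs agreeing within 5 bp and keeps the longest contig
as representative. Breakpoints are reported 1-based inclusive; internal
arithmetic is 0-based half-open.

## Filters

The mononucleotide repeat ratio of a window is (longest single-base run) /
(window length). It is computed over 20 bp windows on each side of the
junction; a side at ≥ 0.6 drops the candidate. The definition is this
package's own (the statistic's published description is not available in
detail); it is deliberately the simplest statistic matching the stated
purpose, and both window and threshold are configurable. Windows truncated
below 4 bp by a contig edge are flagged SHORT_WINDOW and kept. The blocklist
accepts unordered gene pairs or 1-based closed genomic intervals and ships
empty (its content is panel-specific). Each filter evaluates the unfiltered
candidate, so flags are order-independent and the kept set is exactly the
flag-free candidates.

## Frame annotation

Breakpoints snap to the nearest exon boundary within 3 bp (assembler/aligner
jitter); otherwise they are Mid-exon or Intronic. With L5 = coding bases of
the 5′ transcript retained through the junction and P3 = (3′ acceptor offset
− CDS start) mod 3, the fusion is In-frame iff L5 mod 3 = P3 — i.e. the 3′
gene is translated without frame shift. Frame is computed from genomic
breakpoints only, so small junction insertions do not change the verdict.
Non-coding transcripts (NR_ accessions) and mid-exon or unannotated sides
return Indeterminate rather than a guess. When several transcripts contain a
breakpoint the canonical one is preferred, then longest CDS, then id.

## Confirmation and VCF

Constructs take up to 150 bp of genome on each side of the junction
(strand-aware, truncated at chromosome ends; < 20 bp on either side rejects
the construct). Reads that match any panel transcript end-to-end with zero
edits are removed as ordinary transcription before support counting — a
junction-spanning read can never match a single transcript perfectly. A
consensus **molecule** (mate pair counted once) supports a call when its
alignment covers ≥ 10 bases on both sides of the junction at ≥ 90% identity;
because support is counted after UMI consensus, PCR duplication cannot
inflate it. The default evidence threshold is one supporting molecule,
user-configurable. Calls are written as VCF 4.2 paired BND records with
MATEID cross-references and INFO keys GENE5/GENE3, EXON5/EXON3, FRAME, SR,
CONTIG, MRR5/MRR3; the bracket notation encodes the strand orientation of
each partner. The IGV session bundles the construct FASTA (+faidx), a
sorted/indexed BAM of supporting alignments, and a session XML with relative
paths.

## Benchmark metrics

Accuracy and TPR follow the standard confusion-matrix definitions, computed
per sample and aggregated over a read-support cutoff grid of 1–5, 10, 20,
…, 100. A call matches a truth fusion when the unordered gene pair matches
and both breakpoints agree within 10 bp (the matching radius is this
package's choice). A fusion-negative sample with no surviving calls counts
one TN. SMAPE uses denominator (A + F), so a caller that recovers nothing
scores exactly MAPE = SMAPE = 1; the halved-denominator SMAPE variant would
score 2 in that case and is not used. Paired significance testing of SMAPE
values between callers is out of scope here; a standard signed-rank routine
(e.g. `scipy.stats.wilcoxon`) applies directly to the two series.

## The simulator

The generator emulates QIAseq-style amplicon data: each molecule is a
110–150 bp fragment of a (fused or normal) mRNA, receives a unique 12 bp UMI
at the start of R1, and is amplified to 1 + Poisson(dup_rate − 1) copies
(mean = `duplicate_rate`, default 3). Copies differ only by iid substitution
errors (default 1%, applied to template and UMI alike); qualities are drawn
uniformly from Q30–Q40. R1 carries the UMI plus the fragment 5′ end, R2 the
reverse-complemented fragment 3′ end. Fusion fragments always span the
junction by ≥ 25 bp on each side and the first fragment of each truth is
centred so at least one read overlaps the junction by a third of the read
length. Background molecules are drawn uniformly from unfused panel
transcripts — the simplest null for specificity testing. Panels place one
gene per chromosome with 3–6 exons of 170–400 bp and introns of 3–9 kb:
exons are long enough that 150 bp construct flanks stay exonic, and introns
are small enough that contigs crossing one splice junction stay below the
10 kb fusion threshold (so the splice-rejection path is genuinely exercised
by background reads). CDS bounds sit inside the terminal exons with a whole
number of codons.

What the simulator does **not** model: indels, quality-dependent error
profiles, FFPE degradation, rRNA and off-target content, realistic
expression distributions, and multi-transcript genes. Passing the synthetic
end-to-end suites therefore demonstrates the pipeline's logic and
determinism, not clinical performance on FFPE libraries.

## Problem sizes and determinism

The bundled end-to-end studies use a 30-gene panel with 27 planted fusions
(50 molecules each) plus 600 background molecules — roughly 6,000 read
pairs — which the pipeline processes in seconds while exercising every
stage; negative replicates use the same scale without fusions. All
randomness flows through a single seed per run, outputs are sorted at every
merge point, and the per-gene parallel assembly merges results in gene
order, so VCF output is byte-identical across re-runs and thread counts.

## Known limitations

- Substitution-only alignment extension: real indel-rich data would need
  the pluggable external engines (bwa/blat-style) the CLI contracts allow.
- Breakpoint placement inside junction micro-homology is reported at the
  window midpoint; the true exon boundary is recovered by annotation
  snapping (tolerance 3 bp) rather than by the aligner.
- The blocklist ships empty; recurrent-artifact suppression is only as good
  as the panel-specific list supplied.
- Support counting reports distinct consensus molecules; tools that count
  raw reads or read pairs will report systematically different SR values on
  the same data.
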