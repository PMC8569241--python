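"""Alignment-free PCR-duplicate collapsing with Bayesian consensus quality.

Reads are clustered by their unique molecular index (UMI) with a configurable
Hamming tolerance; each cluster is collapsed to one consensus read per mate.
The consensus base at each position maximises the posterior

    P(b | obs) ∝ π_b · Π_i L(obs_i | b),   L = (1 − e_i) if obs_i == b else e_i / 3,

with e_i = 10^(−Q_i/10) from the observed Phred score and a uniform prior
π_b = 1/4 by default. The output Phred score is the capped phred-scaled
posterior error probability −10·log10(1 − P_max), so agreement between
duplicates yields base qualities above the raw instrument values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import FastqRecord, read_fastq, write_fastq

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_N_CODE = 4
UNIFORM_PRIOR = (0.25, 0.25, 0.25, 0.25)


@dataclass
class DedupConfig:
    umi_length: int = 12
    umi_read: str = "R1"
    umi_offset: int = 0
    max_hamming: int = 1
    qual_cap: int = 60
    split_prefix: int = 0  # group clusters additionally by first k template bases

    def __post_init__(self) -> None:
        if self.umi_length > 16:
            raise ValueError("umi_length must be <= 16")
        if self.umi_read not in ("R1", "R2"):
            raise ValueError("umi_read must be 'R1' or 'R2'")


@dataclass
class TaggedRead:
    read_id: str
    bases: str
    quals: list[int]
    mate: str
    umi: str


@dataclass
class UmiCluster:
    representative_umi: str
    members: list  # list of (TaggedRead R1, TaggedRead R2) pairs

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    bases: str
    quals: list[int]
    duplicate_count: int
    source_read_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# UMI primitives


def hamming(u1: str, u2: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(u1) != len(u2):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(a != b for a, b in zip(u1, u2))


def encode_umi(umi: str) -> int:
    """Injective 2-bit-per-base encoding (A=0, C=1, G=2, T=3), length <= 16."""
    if len(umi) > 16:
        raise ValueError("UMI longer than 16 bases cannot be 2-bit encoded in 32 bits")
    code = 0
    for b in umi:
        try:
            code = (code << 2) | _BASE_CODE[b]
        except KeyError:
            raise ValueError(f"non-ACGT base {b!r} in UMI") from None
    return code


def decode_umi(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def cluster_umis(umi_counts: dict[str, int], max_hamming: int) -> dict[str, str]:
    """Greedy count-descending clustering; returns UMI -> representative map.

    Seeds are taken in descending (count, then ascending encoded-UMI) order;
    each seed absorbs every unassigned UMI within ``max_hamming``. UMIs
    containing N are never clustered (their own singletons). By construction
    surviving representatives are pairwise more than ``max_hamming`` apart.
    """
    clean = [u for u in umi_counts if "N" not in u]
    dirty = [u for u in umi_counts if "N" in u]
    assignment = {u: u for u in dirty}
    if not clean:
        return assignment
    order = sorted(clean, key=lambda u: (-umi_counts[u], encode_umi(u)))
    mat = np.frombuffer("".join(order).encode(), dtype=np.uint8).reshape(
        len(order), len(order[0])
    )
    unassigned = np.ones(len(order), dtype=bool)
    for i, seed in enumerate(order):
        if not unassigned[i]:
            continue
        dists = (mat != mat[i]).sum(axis=1)
        hit = unassigned & (dists <= max_hamming)
        for j in np.nonzero(hit)[0]:
            assignment[order[j]] = seed
        unassigned &= ~hit
    return assignment


def cluster_reads(reads: Sequence[TaggedRead], max_hamming: int) -> list[UmiCluster]:
    """Partition tagged reads into UMI clusters (single-end convenience form)."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.umi] = counts.get(r.umi, 0) + 1
    assignment = cluster_umis(counts, max_hamming)
    groups: dict[str, list[TaggedRead]] = {}
    for r in reads:
        groups.setdefault(assignment[r.umi], []).append(r)
    out = []
    for rep in sorted(groups, key=_rep_sort_key):
        out.append(UmiCluster(rep, [(m, None) for m in groups[rep]]))
    return out


def _rep_sort_key(umi: str):
    return (0, encode_umi(umi)) if "N" not in umi else (1, umi)


# ---------------------------------------------------------------------------
# Bayesian consensus


def consensus_base(
    observations: Sequence[tuple[str, int]],
    prior: Sequence[float] = UNIFORM_PRIOR,
    qual_cap: int = 60,
) -> tuple[str, int, list[float]]:
    """Posterior over {A,C,G,T} for one position given (base, Phred) observations.

    Returns (consensus base, output Phred, posterior vector). Ties break
    lexicographically (A < C < G < T). N observations are ignored; all-N
    input yields ('N', 0, uniform posterior).
    """
    if not observations:
        raise ValueError("consensus_base requires at least one observation")
    logpost = [math.log(p) if p > 0 else -math.inf for p in prior]
    informative = False
    for base, q in observations:
        if base == "N":
            continue
        informative = True
        e = min(0.75, 10.0 ** (-q / 10.0))  # Q0 observations stay finite
        for h in range(4):
            logpost[h] += math.log1p(-e) if _BASES[h] == base else math.log(e / 3.0)
    if not informative:
        return "N", 0, [0.25, 0.25, 0.25, 0.25]
    m = max(logpost)
    weights = [math.exp(lp - m) for lp in logpost]
    total = sum(weights)
    post = [w / total for w in weights]
    best = max(range(4), key=lambda h: (post[h], -h))  # argmax, first on ties
    # exact tie -> lexicographically smallest base
    for h in range(4):
        if post[h] >= post[best] - 1e-12:
            best = h
            break
    p_err = max(1.0 - post[best], 1e-300)
    q_out = min(qual_cap, round(-10.0 * math.log10(p_err)))
    return _BASES[best], q_out, post


def _consensus_sequence(
    members: list[tuple[str, list[int]]],
    qual_cap: int,
) -> tuple[str, list[int]]:
    """Vectorised per-position consensus over a cluster's reads of one mate.

    Consensus length is the modal member length (ties -> longer); shorter
    members contribute only to the positions they cover.
    """
    if len(members) == 1:
        bases, quals = members[0]
        return bases, list(quals)
    lengths = [len(b) for b, _ in members]
    counts: dict[int, int] = {}
    for L in lengths:
        counts[L] = counts.get(L, 0) + 1
    length = max(counts, key=lambda L: (counts[L], L))
    m = len(members)
    codes = np.full((m, length), _N_CODE, dtype=np.int8)
    qmat = np.zeros((m, length), dtype=np.float64)
    for i, (bases, quals) in enumerate(members):
        n = min(len(bases), length)
        row = np.frombuffer(bases[:n].encode(), dtype=np.uint8)
        c = np.full(n, _N_CODE, dtype=np.int8)
        for b, k in _BASE_CODE.items():
            c[row == ord(b)] = k
        codes[i, :n] = c
        qmat[i, :n] = quals[:n]
    e = np.minimum(0.75, 10.0 ** (-qmat / 10.0))
    log_match = np.log1p(-e)
    log_mis = np.log(e / 3.0)
    valid = codes != _N_CODE
    loglik = np.zeros((4, length))
    for h in range(4):
        contrib = np.where(codes == h, log_match, log_mis)
        loglik[h] = np.where(valid, contrib, 0.0).sum(axis=0)
    loglik += np.log(0.25)
    mx = loglik.max(axis=0)
    w = np.exp(loglik - mx)
    post = w / w.sum(axis=0)
    # lexicographic tie-break: first index attaining (max - 1e-12)
    best = (post >= post.max(axis=0) - 1e-12).argmax(axis=0)
    p_best = post[best, np.arange(length)]
    any_valid = valid.any(axis=0)
    q_out = np.minimum(
        qual_cap, np.round(-10.0 * np.log10(np.maximum(1.0 - p_best, 1e-300)))
    ).astype(int)
    bases_out = np.array(list(_BASES + "N"), dtype="U1")[
        np.where(any_valid, best, _N_CODE)
    ]
    quals_out = np.where(any_valid, q_out, 0)
    return "".join(bases_out), [int(q) for q in quals_out]


def consensus_from_cluster(
    reads: list[tuple[str, list[int]]],
    read_ids: list[str],
    qual_cap: int = 60,
) -> ConsensusRead:
    bases, quals = _consensus_sequence(reads, qual_cap)
    return ConsensusRead(bases, quals, len(reads), list(read_ids))


# ---------------------------------------------------------------------------
# Full FASTQ dedupe


@dataclass
class DedupResult:
    r1: list[FastqRecord]
    r2: list[FastqRecord]
    stats: dict


def _extract_umi(rec: FastqRecord, cfg: DedupConfig) -> str:
    return rec.bases[cfg.umi_offset : cfg.umi_offset + cfg.umi_length]


def dedupe_records(
    r1: Sequence[FastqRecord],
    r2: Sequence[FastqRecord],
    config: DedupConfig | None = None,
) -> DedupResult:
    """Collapse paired FASTQ records to one consensus pair per UMI cluster.

    Mates must be synchronized (identical ids in identical order). The
    consensus R1 keeps the UMI-bearing read structure: its UMI slice is the
    cluster's representative UMI, so deduplication is idempotent — re-running
    it on its own output finds only singleton clusters and passes reads
    through unchanged. Output order is deterministic (ascending encoded
    representative UMI, N-containing UMIs last).
    """
    cfg = config or DedupConfig()
    if len(r1) != len(r2):
        raise ValueError("R1/R2 record counts differ")
    for a, b in zip(r1, r2):
        if a.read_id != b.read_id:
            raise ValueError(f"desynchronized mates at read {a.read_id!r}")

    umi_reads = r1 if cfg.umi_read == "R1" else r2
    umis = [_extract_umi(rec, cfg) for rec in umi_reads]
    counts: dict[str, int] = {}
    for u in umis:
        counts[u] = counts.get(u, 0) + 1
    assignment = cluster_umis(counts, cfg.max_hamming)

    groups: dict[tuple, list[int]] = {}
    for i, u in enumerate(umis):
        key: tuple = (assignment[u],)
        if cfg.split_prefix > 0:
            tagged = r1[i] if cfg.umi_read == "R1" else r2[i]
            tpl_start = cfg.umi_offset + cfg.umi_length
            key = (assignment[u], tagged.bases[tpl_start : tpl_start + cfg.split_prefix])
        groups.setdefault(key, []).append(i)

    out1: list[FastqRecord] = []
    out2: list[FastqRecord] = []
    sizes = []
    for gi, key in enumerate(sorted(groups, key=lambda k: _rep_sort_key(k[0]) + k[1:])):
        idx = groups[key]
        rep = key[0]
        ids = [r1[i].read_id for i in idx]
        c1 = consensus_from_cluster(
            [(r1[i].bases, r1[i].quals) for i in idx], ids, cfg.qual_cap
        )
        c2 = consensus_from_cluster(
            [(r2[i].bases, r2[i].quals) for i in idx], ids, cfg.qual_cap
        )
        # restore the representative UMI verbatim in the UMI-bearing mate
        target = c1 if cfg.umi_read == "R1" else c2
        o = cfg.umi_offset
        if len(target.bases) >= o + cfg.umi_length:
            target.bases = target.bases[:o] + rep + target.bases[o + cfg.umi_length :]
        name = f"UMI_{rep}_{gi:05d}" if cfg.split_prefix else f"UMI_{rep}"
        if len(idx) == 1:  # single-read clusters pass through unchanged
            out1.append(FastqRecord(name, r1[idx[0]].bases, list(r1[idx[0]].quals)))
            out2.append(FastqRecord(name, r2[idx[0]].bases, list(r2[idx[0]].quals)))
        else:
            out1.append(FastqRecord(name, c1.bases, c1.quals))
            out2.append(FastqRecord(name, c2.bases, c2.quals))
        sizes.append(len(idx))
    stats = {
        "input_reads": 2 * len(r1),
        "input_pairs": len(r1),
        "clusters": len(sizes),
        "mean_duplicate_count": float(np.mean(sizes)) if sizes else 0.0,
    }
    return DedupResult(out1, out2, stats)


def dedupe(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    out_r1: str | Path,
    out_r2: str | Path,
    config: DedupConfig | None = None,
    stats_path: str | Path | None = None,
) -> dict:
    """File-level dedupe: FASTQ in, consensus FASTQ + stats JSON out."""
    res = dedupe_records(list(read_fastq(fastq_r1)), list(read_fastq(fastq_r2)), config)
    write_fastq(res.r1, out_r1)
    write_fastq(res.r2, out_r2)
    if stats_path:
        Path(stats_path).write_text(json.dumps(res.stats, indent=2))
    return res.stats
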