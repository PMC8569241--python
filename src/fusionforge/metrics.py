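"""Benchmark statistics: accuracy, TPR, MAPE/SMAPE and read-support sweeps.

Definitions:
    accuracy = (TP + TN) / (TP + TN + FP + FN)
    TPR      = TP / (TP + FN)
    MAPE     = mean(|A − F| / A)            over fusions with known support A > 0
    SMAPE    = mean(|A − F| / (A + F))      (0/0 := 0; always in [0, 1])

The SMAPE denominator is (A + F), not (A + F)/2, so a caller detecting zero
supporting reads for every known fusion scores exactly MAPE = SMAPE = 1.
A call matches a truth fusion when the unordered gene pair matches and both
breakpoints agree within a 10-base window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

DEFAULT_CUTOFFS = (1, 2, 3, 4, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass
class BenchmarkCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


def accuracy(counts: BenchmarkCounts) -> float:
    total = counts.TP + counts.TN + counts.FP + counts.FN
    if total == 0:
        raise ValueError("accuracy undefined for all-zero counts")
    return (counts.TP + counts.TN) / total


def tpr(counts: BenchmarkCounts) -> float:
    if counts.TP + counts.FN == 0:
        raise ValueError("TPR undefined when TP + FN == 0")
    return counts.TP / (counts.TP + counts.FN)


def mape(series: Sequence[tuple[float, float]]) -> float:
    """Mean absolute percentage error over (actual A, forecast F) pairs."""
    if not series:
        raise ValueError("empty series")
    if any(a <= 0 for a, _ in series):
        raise ValueError("MAPE requires all actual values > 0")
    return sum(abs(a - f) / a for a, f in series) / len(series)


def smape(series: Sequence[tuple[float, float]]) -> float:
    """Symmetric MAPE with denominator (A + F); bounded by [0, 1]."""
    if not series:
        raise ValueError("empty series")
    if any(a <= 0 for a, _ in series):
        raise ValueError("SMAPE requires all actual values > 0")
    total = 0.0
    for a, f in series:
        denom = a + f
        total += abs(a - f) / denom if denom > 0 else 0.0
    return total / len(series)


@dataclass(frozen=True)
class CallRecord:
    """One fusion call, reduced to the fields benchmarking needs."""

    sample: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    chrom3: str
    pos3: int
    sr: int


@dataclass(frozen=True)
class TruthRecord:
    sample: str
    fusion_id: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    chrom3: str
    pos3: int
    n_support: int = 1


def matches(call: CallRecord, truth: TruthRecord, window: int = 10) -> bool:
    """Unordered gene-pair match with breakpoints within ``window`` bases."""
    direct = (
        {call.gene5, call.gene3} == {truth.gene5, truth.gene3}
        and call.chrom5 == truth.chrom5
        and abs(call.pos5 - truth.pos5) <= window
        and call.chrom3 == truth.chrom3
        and abs(call.pos3 - truth.pos3) <= window
    )
    swapped = (
        {call.gene5, call.gene3} == {truth.gene5, truth.gene3}
        and call.chrom5 == truth.chrom3
        and abs(call.pos5 - truth.pos3) <= window
        and call.chrom3 == truth.chrom5
        and abs(call.pos3 - truth.pos5) <= window
    )
    return direct or swapped


def sample_counts(
    calls: Sequence[CallRecord],
    truths: Sequence[TruthRecord],
    cutoff: int = 1,
    window: int = 10,
) -> BenchmarkCounts:
    """TP/FP/FN/TN for one sample at one read-support cutoff.

    TN is 1 for a fusion-negative sample with no surviving calls, else 0
    (the per-sample negative-control convention).
    """
    pos_calls = [c for c in calls if c.sr >= cutoff]
    tp = fn = 0
    for t in truths:
        if any(matches(c, t, window) for c in pos_calls):
            tp += 1
        else:
            fn += 1
    fp = sum(1 for c in pos_calls if not any(matches(c, t, window) for t in truths))
    tn = 1 if (not truths and not pos_calls) else 0
    return BenchmarkCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def threshold_sweep(
    calls: Sequence[CallRecord],
    truths: Sequence[TruthRecord],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    window: int = 10,
) -> pd.DataFrame:
    """Accuracy and TPR per read-support cutoff, aggregated over samples."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be ascending")
    samples = sorted({c.sample for c in calls} | {t.sample for t in truths})
    rows = []
    for cutoff in cutoffs:
        agg = BenchmarkCounts()
        for s in samples:
            cts = sample_counts(
                [c for c in calls if c.sample == s],
                [t for t in truths if t.sample == s],
                cutoff=cutoff,
                window=window,
            )
            agg = BenchmarkCounts(agg.TP + cts.TP, agg.TN + cts.TN,
                                  agg.FP + cts.FP, agg.FN + cts.FN)
        total = agg.TP + agg.TN + agg.FP + agg.FN
        rows.append(
            {
                "cutoff": cutoff,
                "TP": agg.TP, "TN": agg.TN, "FP": agg.FP, "FN": agg.FN,
                "accuracy": accuracy(agg) if total else float("nan"),
                "tpr": tpr(agg) if agg.TP + agg.FN else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def read_vcf_calls(path, sample: str = "sample") -> list[CallRecord]:
    """Load paired-BND fusion calls back from a VCF file."""
    import pysam

    records = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            records[rec.id] = rec
    calls = []
    for rid, rec in sorted(records.items()):
        if not rid.endswith("_1"):
            continue
        mate = records.get(str(rec.info["MATEID"]))
        if mate is None:
            raise ValueError(f"unpaired BND record {rid}")
        calls.append(
            CallRecord(
                sample=sample,
                gene5=str(rec.info["GENE5"]),
                gene3=str(rec.info["GENE3"]),
                chrom5=rec.chrom,
                pos5=rec.pos,
                chrom3=mate.chrom,
                pos3=mate.pos,
                sr=int(rec.info["SR"]),
            )
        )
    return calls


def truths_from_table(df: pd.DataFrame, sample: str = "sample") -> list[TruthRecord]:
    """TruthRecords from the simulator's truth table (one row per fusion)."""
    out = []
    for row in df.itertuples():
        out.append(
            TruthRecord(
                sample=sample,
                fusion_id=str(row.fusion_id),
                gene5=str(row.gene5),
                gene3=str(row.gene3),
                chrom5=str(row.chrom5),
                pos5=int(row.pos5),
                chrom3=str(row.chrom3),
                pos3=int(row.pos3),
                n_support=int(getattr(row, "n_molecules", 1)),
            )
        )
    return out


def support_series(
    calls: Sequence[CallRecord],
    truths: Sequence[TruthRecord],
    window: int = 10,
) -> list[tuple[float, float]]:
    """(known support A, detected support F) per truth fusion; F=0 if missed."""
    series = []
    for t in truths:
        hit = [c.sr for c in calls if c.sample == t.sample and matches(c, t, window)]
        series.append((float(t.n_support), float(max(hit) if hit else 0)))
    return series
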