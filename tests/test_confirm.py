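"""Chimeric-construct confirmation, VCF breakends, IGV session."""

import pysam
import pytest

from fusionforge.confirm import (build_construct, confirm_candidates,
                                 count_support, emit_vcf, igv_session,
                                 remove_known_transcript_reads, FusionCall)
from fusionforge.discovery import BreakpointCandidate, SegmentAlignment
from fusionforge.io import FastqRecord
from fusionforge.models import revcomp
from conftest import random_seq


@pytest.fixture(scope="module")
def genome():
    import numpy as np

    rng = np.random.default_rng(31)
    return {
        "chr1": random_seq(rng, 4000),
        "chr2": random_seq(rng, 4000),
    }


def _cand(bp5, bp3, contig="A" * 160, gene5="GA", gene3="GB"):
    s5 = SegmentAlignment("c", 0, 80, bp5[0], 0, 80, bp5[2], 1.0)
    s3 = SegmentAlignment("c", 80, len(contig), bp3[0], 0, 80, bp3[2], 1.0)
    c = BreakpointCandidate("c", contig, 80, s5, s3, bp5, bp3)
    c.gene5, c.gene3 = gene5, gene3
    return c


class TestRemoveKnownTranscriptReads:
    def test_perfect_transcript_read_removed(self, rng):
        tx = {"G": random_seq(rng, 400)}
        reads = [FastqRecord("a", tx["G"][50:130], [30] * 80)]
        assert remove_known_transcript_reads(reads, tx) == []

    def test_reverse_complement_also_removed(self, rng):
        tx = {"G": random_seq(rng, 400)}
        reads = [FastqRecord("a", revcomp(tx["G"][50:130]), [30] * 80)]
        assert remove_known_transcript_reads(reads, tx) == []

    def test_one_mismatch_retained(self, rng):
        tx = {"G": random_seq(rng, 400)}
        bases = list(tx["G"][50:130])
        bases[40] = "A" if bases[40] != "A" else "C"
        reads = [FastqRecord("a", "".join(bases), [30] * 80)]
        assert len(remove_known_transcript_reads(reads, tx)) == 1

    def test_junction_read_retained(self, rng):
        tx = {"G1": random_seq(rng, 400), "G2": random_seq(rng, 400)}
        chimera = tx["G1"][300:350] + tx["G2"][0:50]
        reads = [FastqRecord("a", chimera, [30] * 100)]
        assert len(remove_known_transcript_reads(reads, tx)) == 1


class TestBuildConstruct:
    def test_deep_breakpoints_full_flanks(self, genome):
        cand = _cand(("chr1", 2000, "+"), ("chr2", 2000, "+"))
        c = build_construct(cand, genome, flank=150)
        assert len(c.sequence) == 300
        assert c.junction_index == 150
        assert c.sequence[:150] == genome["chr1"][1850:2000]
        assert c.sequence[150:] == genome["chr2"][1999:2149]

    def test_minus_strand_flanks(self, genome):
        cand = _cand(("chr1", 2000, "-"), ("chr2", 2000, "-"))
        c = build_construct(cand, genome, flank=150)
        assert c.sequence[:150] == revcomp(genome["chr1"][1999:2149])
        assert c.sequence[150:] == revcomp(genome["chr2"][1850:2000])

    def test_truncation_at_chromosome_end(self, genome):
        cand = _cand(("chr1", 2000, "+"), ("chr2", 3921, "+"))
        c = build_construct(cand, genome, flank=150)
        assert len(c.sequence) == 230
        assert c.junction_index == 150

    def test_short_flank_rejected(self, genome):
        cand = _cand(("chr1", 10, "+"), ("chr2", 2000, "+"))
        assert build_construct(cand, genome, flank=150) is None
        assert "SHORT_CONSTRUCT" in cand.filter_flags

    def test_same_gene_needs_allowlist(self, genome):
        cand = _cand(("chr1", 2000, "+"), ("chr1", 3000, "+"),
                     gene5="G", gene3="G")
        assert build_construct(cand, genome) is None
        cand2 = _cand(("chr1", 2000, "+"), ("chr1", 3000, "+"),
                      gene5="G", gene3="G")
        assert build_construct(cand2, genome, allowlist_genes={"G"}) is not None


class TestCountSupport:
    @pytest.fixture()
    def construct(self, genome):
        cand = _cand(("chr1", 2000, "+"), ("chr2", 2000, "+"))
        return build_construct(cand, genome, flank=150)

    def test_overhang_threshold(self, construct):
        """Reads spanning >= 10 bases past the junction support; 9 does not."""
        j = construct.junction_index
        for overhang, expect in [(9, 0), (10, 1), (20, 1)]:
            read = FastqRecord(
                "r", construct.sequence[j - 60 : j + overhang], [30] * (60 + overhang)
            )
            count, _ = count_support([read], construct, min_span=10)
            assert count == expect, overhang

    def test_flank_only_read_not_supporting(self, construct):
        read = FastqRecord("r", construct.sequence[10:110], [30] * 100)
        count, alns = count_support([read], construct)
        assert count == 0
        assert len(alns) == 1 and not alns[0].supporting

    def test_reverse_complement_read_supports(self, construct):
        j = construct.junction_index
        read = FastqRecord(
            "r", revcomp(construct.sequence[j - 40 : j + 40]), [30] * 80
        )
        count, _ = count_support([read], construct)
        assert count == 1

    def test_pair_counts_once(self, construct):
        j = construct.junction_index
        r1 = FastqRecord("m/1", construct.sequence[j - 50 : j + 30], [30] * 80)
        r2 = FastqRecord("m/2", construct.sequence[j - 30 : j + 50], [30] * 80)
        count, _ = count_support([r1, r2], construct)
        assert count == 1

    def test_low_identity_rejected(self, construct, rng):
        j = construct.junction_index
        count, _ = count_support(
            [FastqRecord("r", random_seq(rng, 80), [30] * 80)], construct
        )
        assert count == 0


def _call(genome, n=1, sr=3):
    cand = _cand(("chr1", 2000 + 111 * n, "+"), ("chr2", 1000 + 77 * n, "-"))
    construct = build_construct(cand, genome)
    cand.supporting_read_count = sr
    return FusionCall(cand, construct, sr, [f"m{i}" for i in range(sr)])


class TestEmitVcf:
    def test_paired_bnd_records(self, genome, tmp_path):
        text = emit_vcf([_call(genome)], genome)
        path = tmp_path / "calls.vcf"
        path.write_text(text)
        with pysam.VariantFile(str(path)) as vf:
            recs = {r.id: r for r in vf}
        assert len(recs) == 2
        (a, b) = sorted(recs.values(), key=lambda r: r.id)
        assert a.info["MATEID"] == b.id and b.info["MATEID"] == a.id
        assert a.info["SVTYPE"] == "BND"
        assert "[" in str(a.alts[0]) or "]" in str(a.alts[0])

    def test_round_trip_fields(self, genome, tmp_path):
        call = _call(genome, sr=5)
        call.candidate.gene5, call.candidate.gene3 = "GA", "GB"
        path = tmp_path / "c.vcf"
        path.write_text(emit_vcf([call], genome))
        from fusionforge.metrics import read_vcf_calls

        (rec,) = read_vcf_calls(path)
        assert (rec.gene5, rec.gene3, rec.sr) == ("GA", "GB", 5)
        assert (rec.chrom5, rec.pos5) == call.candidate.breakpoint5[:2]
        assert (rec.chrom3, rec.pos3) == call.candidate.breakpoint3[:2]

    def test_empty_call_set_is_valid_vcf(self, genome, tmp_path):
        path = tmp_path / "e.vcf"
        path.write_text(emit_vcf([], genome))
        with pysam.VariantFile(str(path)) as vf:
            assert list(vf) == []

    def test_records_sorted(self, genome, tmp_path):
        text = emit_vcf([_call(genome, n) for n in (3, 1, 2)], genome)
        path = tmp_path / "s.vcf"
        path.write_text(text)
        with pysam.VariantFile(str(path)) as vf:
            rows = [(r.chrom, r.pos) for r in vf]
        assert rows == sorted(rows)


class TestConfirmCandidates:
    def test_support_monotone_in_threshold(self, genome, rng):
        cand = _cand(("chr1", 2000, "+"), ("chr2", 2000, "+"))
        junction = genome["chr1"][1850:2000] + genome["chr2"][1999:2149]
        reads = [
            FastqRecord(f"m{i}", junction[150 - 50 - i : 150 + 30 + i], [30] * (80 + 2 * i))
            for i in range(4)
        ]
        counts = {}
        for ms in (1, 2, 4, 5):
            calls = confirm_candidates([cand], genome, reads, {"T": "ACGT" * 50},
                                       min_support=ms)
            counts[ms] = len(calls)
        assert counts[1] == counts[2] == counts[4] == 1
        assert counts[5] == 0


class TestIgvSession:
    def test_session_files(self, genome, tmp_path):
        call = _call(genome, sr=0)
        j = call.construct.junction_index
        reads = [
            FastqRecord(f"m{i}", call.construct.sequence[j - 40 : j + 40], [30] * 80)
            for i in range(5)
        ]
        call.supporting_read_count, alns = count_support(reads, call.construct)
        call.alignments = alns
        out = igv_session([call], tmp_path)
        assert out["fasta"].exists() and out["bam"].exists() and out["session"].exists()
        with pysam.AlignmentFile(str(out["bam"])) as bam:
            assert sum(1 for _ in bam) == 5
        import xml.etree.ElementTree as ET

        root = ET.parse(out["session"]).getroot()
        assert root.tag == "Session"
        assert root.find("Resources") is not None
        assert root.find("Panel") is not None

    def test_empty_calls_no_session(self, tmp_path):
        assert igv_session([], tmp_path) is None
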