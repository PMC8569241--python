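"""Split alignment of contigs and breakpoint candidate calling."""

import pytest

from fusionforge.assembly import Contig
from fusionforge.discovery import (GenomeIndex, call_candidates,
                                   collapse_redundant, flipped, split_align)
from fusionforge.models import revcomp
from conftest import random_seq


@pytest.fixture(scope="module")
def genome():
    import numpy as np

    rng = np.random.default_rng(77)
    return {
        "chrA": random_seq(rng, 30000),
        "chrB": random_seq(rng, 30000),
    }


@pytest.fixture(scope="module")
def gindex(genome):
    return GenomeIndex(genome, k=17)


def _contig(seq, cid="c1"):
    return Contig(cid, "g", seq, [cid])


def _lcp(a, b):
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _lcs(a, b):
    return _lcp(a[::-1], b[::-1])


class TestSplitAlign:
    def test_exact_substring_single_segment(self, genome, gindex):
        contig = _contig(genome["chrA"][1000:1160])
        segs = split_align(contig, genome, gindex)
        assert len(segs) == 1
        s = segs[0]
        assert (s.chromosome, s.genome_start, s.genome_end) == ("chrA", 1000, 1160)
        assert (s.contig_start, s.contig_end, s.strand) == (0, 160, "+")

    def test_chimeric_contig_two_segments(self, genome, gindex):
        contig = _contig(genome["chrA"][1000:1080] + genome["chrB"][5000:5080])
        segs = split_align(contig, genome, gindex)
        assert len(segs) == 2
        by_chrom = {s.chromosome: s for s in segs}
        # segments may extend past the junction by exactly the micro-homology
        # between the partner sequence and the reference continuation
        h_a = _lcp(genome["chrB"][5000:5080], genome["chrA"][1080:1160])
        h_b = _lcs(genome["chrA"][1000:1080], genome["chrB"][4920:5000])
        assert (by_chrom["chrA"].contig_start, by_chrom["chrA"].contig_end) == (0, 80 + h_a)
        assert (by_chrom["chrB"].contig_start, by_chrom["chrB"].contig_end) == (80 - h_b, 160)

    def test_reverse_complement_flips_strand(self, genome, gindex):
        fwd = _contig(genome["chrA"][1000:1160])
        rev = _contig(revcomp(genome["chrA"][1000:1160]))
        sf = split_align(fwd, genome, gindex)[0]
        sr = split_align(rev, genome, gindex)[0]
        assert (sr.genome_start, sr.genome_end) == (sf.genome_start, sf.genome_end)
        assert {sf.strand, sr.strand} == {"+", "-"}

    def test_short_contig_warns(self, genome, gindex):
        with pytest.warns(UserWarning):
            assert split_align(_contig("ACGTACGT"), genome, gindex) == []

    def test_tolerates_substitutions(self, genome, gindex):
        seq = list(genome["chrA"][2000:2150])
        seq[40] = "A" if seq[40] != "A" else "C"
        seq[100] = "A" if seq[100] != "A" else "C"
        segs = split_align(_contig("".join(seq)), genome, gindex)
        assert len(segs) == 1
        assert segs[0].length == 150
        assert segs[0].identity >= 149 / 150 - 0.02


class TestCallCandidates:
    def test_single_segment_no_candidate(self, genome, gindex):
        contig = _contig(genome["chrA"][1000:1160])
        segs = split_align(contig, genome, gindex)
        assert call_candidates(contig, segs) == []

    def test_cross_chromosome_candidate(self, genome, gindex):
        contig = _contig(genome["chrA"][1000:1080] + genome["chrB"][5000:5080])
        segs = split_align(contig, genome, gindex)
        cands = call_candidates(contig, segs)
        assert len(cands) == 1
        c = cands[0]
        # micro-homology at the junction shifts the reported breakpoints by at
        # most half the ambiguity window (junction placed mid-overlap)
        h_a = _lcp(genome["chrB"][5000:5080], genome["chrA"][1080:1160])
        h_b = _lcs(genome["chrA"][1000:1080], genome["chrB"][4920:5000])
        a_end, b_start = 80 + h_a, 80 - h_b
        junction = a_end if b_start >= a_end else (b_start + a_end) // 2
        assert c.junction_offset == junction
        assert c.breakpoint5 == ("chrA", 1000 + junction, "+")
        assert c.breakpoint3 == ("chrB", 4921 + junction, "+")
        assert abs(c.breakpoint5[1] - 1080) <= 2
        assert abs(c.breakpoint3[1] - 5001) <= 2

    def test_intron_scale_gap_rejected(self, genome, gindex):
        # 500-base genomic gap on one chromosome: splice, not fusion
        contig = _contig(genome["chrA"][1000:1080] + genome["chrA"][1580:1660])
        segs = split_align(contig, genome, gindex)
        assert len(segs) == 2
        assert call_candidates(contig, segs, min_genomic_gap=10000) == []
        assert len(call_candidates(contig, segs, min_genomic_gap=100)) == 1

    def test_strand_change_is_noncontiguous(self, genome, gindex):
        contig = _contig(
            genome["chrA"][1000:1080] + revcomp(genome["chrA"][1500:1580])
        )
        segs = split_align(contig, genome, gindex)
        cands = call_candidates(contig, segs)
        assert len(cands) >= 1
        assert {cands[0].breakpoint5[2], cands[0].breakpoint3[2]} == {"+", "-"}

    def test_junction_sequence_round_trip(self, genome, gindex):
        """Re-deriving flank sequence from the segments reproduces the contig."""
        contig = _contig(genome["chrA"][3000:3080] + genome["chrB"][9000:9080])
        segs = split_align(contig, genome, gindex)
        (c,) = call_candidates(contig, segs)
        chrom5, pos5, strand5 = c.breakpoint5
        chrom3, pos3, strand3 = c.breakpoint3
        assert strand5 == strand3 == "+"
        left = genome[chrom5][pos5 - c.junction_offset : pos5]
        right = genome[chrom3][pos3 - 1 : pos3 - 1 + (160 - c.junction_offset)]
        assert left + right == contig.sequence


class TestFlipped:
    def test_involution(self, genome, gindex):
        contig = _contig(genome["chrA"][1000:1080] + genome["chrB"][5000:5080])
        segs = split_align(contig, genome, gindex)
        (c,) = call_candidates(contig, segs)
        f = flipped(c)
        assert f.breakpoint5 == (c.breakpoint3[0], c.breakpoint3[1], "-")
        assert f.contig_sequence == revcomp(c.contig_sequence)
        ff = flipped(f)
        assert ff.breakpoint5 == c.breakpoint5
        assert ff.contig_sequence == c.contig_sequence
        assert ff.junction_offset == c.junction_offset


class TestCollapseRedundant:
    def _cand(self, cid, pos5, pos3, seqlen=160):
        contig = _contig("A" * seqlen, cid)
        segs = []
        from fusionforge.discovery import BreakpointCandidate, SegmentAlignment

        s5 = SegmentAlignment(cid, 0, 80, "chrA", pos5 - 80, pos5, "+", 1.0)
        s3 = SegmentAlignment(cid, 80, seqlen, "chrB", pos3 - 1,
                              pos3 - 1 + seqlen - 80, "+", 1.0)
        return BreakpointCandidate(cid, contig.sequence, 80, s5, s3,
                                   ("chrA", pos5, "+"), ("chrB", pos3, "+"))

    def test_identical_breakpoints_merge(self):
        out = collapse_redundant([self._cand("c1", 500, 900),
                                  self._cand("c2", 500, 900, seqlen=200)])
        assert len(out) == 1
        assert sorted(out[0].member_contig_ids) == ["c1", "c2"]
        assert out[0].contig_id == "c2"  # longest contig represents

    def test_within_window_merge(self):
        out = collapse_redundant([self._cand("c1", 500, 900),
                                  self._cand("c2", 503, 898)], merge_window=5)
        assert len(out) == 1

    def test_distant_kept_separate(self):
        out = collapse_redundant([self._cand("c1", 500, 900),
                                  self._cand("c2", 550, 900)], merge_window=5)
        assert len(out) == 2


class TestEndToEndBreakpointAccuracy:
    def test_planted_fusions_within_two_bases(self, panel, truths, e2e):
        """Every planted fusion yields a call within +/-2 bases of truth."""
        for truth in truths:
            best = None
            for call in e2e.calls:
                c = call.candidate
                for bp5, bp3 in ((c.breakpoint5, c.breakpoint3),
                                 (c.breakpoint3, c.breakpoint5)):
                    if bp5[0] == truth.breakpoint5[0] and bp3[0] == truth.breakpoint3[0]:
                        d = max(abs(bp5[1] - truth.breakpoint5[1]),
                                abs(bp3[1] - truth.breakpoint3[1]))
                        best = d if best is None else min(best, d)
            assert best is not None and best <= 2, truth.fusion_id
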