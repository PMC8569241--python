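"""UMI clustering and Bayesian consensus deduplication."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionforge.dedup import (DedupConfig, cluster_reads, consensus_base,
                               decode_umi, dedupe_records, encode_umi,
                               hamming, TaggedRead)
from fusionforge.io import FastqRecord
from fusionforge.simulate import SimConfig, make_panel, plant_fusion, simulate_reads

# ---------------------------------------------------------------------------
# independent brute-force Bayes oracle


def oracle_posterior(observations, prior=(0.25,) * 4):
    """Direct product-form Bayes over the four base hypotheses."""
    bases = "ACGT"
    post = []
    for h in bases:
        p = prior[bases.index(h)]
        for b, q in observations:
            if b == "N":
                continue
            e = min(0.75, 10 ** (-q / 10))
            p *= (1 - e) if b == h else e / 3
        post.append(p)
    total = sum(post)
    return [p / total for p in post]


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)]
    )
    def test_examples(self, a, b, d):
        assert hamming(a, b) == d
        assert hamming(b, a) == d

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            hamming("ACG", "ACGT")


class TestEncodeUmi:
    def test_single_base_map(self):
        assert [encode_umi(b) for b in "ACGT"] == [0, 1, 2, 3]

    @given(st.text(alphabet="ACGT", min_size=12, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, umi):
        assert decode_umi(encode_umi(umi), 12) == umi

    def test_too_long(self):
        with pytest.raises(ValueError):
            encode_umi("ACGTACGTACGTACGTA")

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            encode_umi("ACGN")


def _reads(umis):
    return [
        TaggedRead(f"r{i}", "ACGT", [30] * 4, "R1", u) for i, u in enumerate(umis)
    ]


class TestClusterReads:
    def test_identical_umis_one_cluster(self):
        clusters = cluster_reads(_reads(["AAAA"] * 5), max_hamming=1)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_absorbs_within_hamming(self):
        # brute-force all-pairs check: AAAT is within 1 of the dominant AAAA
        clusters = cluster_reads(_reads(["AAAA"] * 3 + ["AAAT"]), max_hamming=1)
        assert len(clusters) == 1
        assert clusters[0].representative_umi == "AAAA"
        assert clusters[0].size == 4

    def test_distant_umis_stay_separate(self):
        clusters = cluster_reads(_reads(["AAAA", "TTTT"]), max_hamming=1)
        assert len(clusters) == 2

    def test_partition(self):
        umis = ["AAAA", "AAAT", "AATT", "GGGG", "GGGT", "CCCC"]
        clusters = cluster_reads(_reads(umis * 2), max_hamming=1)
        ids = [r.read_id for c in clusters for r, _ in c.members]
        assert sorted(ids) == sorted(f"r{i}" for i in range(len(umis) * 2))

    def test_n_umis_are_singletons(self):
        clusters = cluster_reads(_reads(["ANAA", "ANAA", "AAAA"]), max_hamming=2)
        reps = {c.representative_umi: c.size for c in clusters}
        assert reps["ANAA"] == 2 or len(clusters) >= 2


class TestConsensusBase:
    def test_single_observation_reproduces_quality(self):
        base, q, post = consensus_base([("C", 20)])
        assert base == "C"
        assert q == 20
        assert post[1] == pytest.approx(0.99)

    def test_agreement_raises_quality(self):
        base, q, post = consensus_base([("A", 30)] * 3)
        assert base == "A"
        oracle = oracle_posterior([("A", 30)] * 3)
        assert post == pytest.approx(oracle, abs=1e-12)
        assert q > 30

    def test_tie_breaks_lexicographic(self):
        base, _, post = consensus_base([("A", 25), ("G", 25)])
        assert base == "A"
        assert post[0] == pytest.approx(post[2], abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_base([])

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT"), st.integers(2, 41)),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_posterior_normalised_and_matches_oracle(self, obs):
        _, _, post = consensus_base(obs)
        assert sum(post) == pytest.approx(1.0, abs=1e-9)
        assert post == pytest.approx(oracle_posterior(obs), abs=1e-9)

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT"), st.integers(2, 41)),
            min_size=1, max_size=5,
        ),
        st.integers(2, 41),
    )
    @settings(max_examples=100, deadline=None)
    def test_agreeing_observation_is_monotone(self, obs, q):
        base, _, post = consensus_base(obs)
        _, _, post2 = consensus_base(obs + [(base, q)])
        i = "ACGT".index(base)
        assert post2[i] >= post[i] - 1e-12


def _pairs(n, bases="ACGTACGTACGT" + "AC" * 30, umi="ACGTACGTACGT"):
    r1 = [FastqRecord(f"p{i}", umi + bases, [33] * (12 + len(bases))) for i in range(n)]
    r2 = [FastqRecord(f"p{i}", bases, [33] * len(bases)) for i in range(n)]
    return r1, r2


class TestDedupe:
    def test_exact_copies_collapse(self):
        r1, r2 = _pairs(10)
        res = dedupe_records(r1, r2)
        assert len(res.r1) == 1
        assert res.stats["clusters"] == 1
        assert res.stats["mean_duplicate_count"] == 10

    def test_no_noise_simulation_yields_one_pair_per_molecule(self):
        panel = make_panel(3, seed=2)
        truth = plant_fusion(panel, *panel.gene_names[:2], 1, 2, n_molecules=6)
        cfg = SimConfig(seed=3, error_rate=0.0, duplicate_rate=3.0,
                        n_background_molecules=5)
        r1, r2, mols = simulate_reads(panel, [truth], cfg)
        res = dedupe_records(r1, r2)
        assert len(res.r1) == len(mols)

    def test_single_read_cluster_passes_through(self):
        r1 = [FastqRecord("x", "ACGTACGTACGT" + "TTGG" * 10, [2, 40] * 26)]
        r2 = [FastqRecord("x", "CCAA" * 10, [7, 13] * 20)]
        res = dedupe_records(r1, r2)
        assert res.r1[0].bases == r1[0].bases
        assert res.r1[0].quals == r1[0].quals
        assert res.r2[0].quals == r2[0].quals

    def test_idempotent(self, panel, truths, sim):
        d1 = dedupe_records(sim["r1"], sim["r2"])
        d2 = dedupe_records(d1.r1, d1.r2)
        assert [(r.read_id, r.bases, r.quals) for r in d1.r1] == [
            (r.read_id, r.bases, r.quals) for r in d2.r1
        ]
        assert [(r.bases, r.quals) for r in d1.r2] == [
            (r.bases, r.quals) for r in d2.r2
        ]

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_cluster_consensus_matches_exhaustive_oracle(self, data):
        """Consensus over <=6 reads x <=8 positions equals brute-force Bayes."""
        from fusionforge.dedup import consensus_from_cluster

        m = data.draw(st.integers(2, 6))
        L = data.draw(st.integers(2, 8))
        reads = []
        for _ in range(m):
            bases = data.draw(st.text(alphabet="ACGT", min_size=L, max_size=L))
            quals = data.draw(
                st.lists(st.integers(2, 41), min_size=L, max_size=L)
            )
            reads.append((bases, quals))
        cons = consensus_from_cluster(reads, [f"r{i}" for i in range(m)])
        expect = "".join(
            oracle_consensus([(b[i], q[i]) for b, q in reads])
            for i in range(L)
        )
        assert cons.bases == expect
        assert cons.duplicate_count == m

    def test_desynchronized_mates_error(self):
        r1 = [FastqRecord("a", "ACGTACGTACGTAAAA", [30] * 16)]
        r2 = [FastqRecord("b", "TTTT", [30] * 4)]
        with pytest.raises(ValueError, match="a"):
            dedupe_records(r1, r2)


def oracle_consensus(observations):
    post = oracle_posterior(observations)
    m = max(post)
    for i, p in enumerate(post):
        if p >= m - 1e-12:
            return "ACGT"[i]
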