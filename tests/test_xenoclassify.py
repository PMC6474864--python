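"""Classifier tests: canonicalization, hand-enumerated categories, retention."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenosplit.synthetic_data import CohortDesign, simulate_counts, simulate_reads
from xenosplit.xenoclassify import (
    CATEGORIES,
    KmerIndex,
    ReadClassification,
    build_index,
    canonical,
    classify_batch,
    classify_read,
    encode_seq,
    kmers_of_reads,
    kmers_of_sequence,
    select_human,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def brute_force_canonical_kmers(seq: str, k: int) -> set:
    """Independent oracle: string k-mers, canonicalized lexicographically."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, revcomp(km)))
    return out


def decode_kmer(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(bases))


class TestKmerPrimitives:
    @given(st.text(alphabet="ACGT", min_size=5, max_size=40), st.sampled_from([3, 5, 7]))
    @settings(max_examples=100, deadline=None)
    def test_sequence_kmers_match_string_oracle(self, seq, k):
        got = {decode_kmer(int(c), k) for c in kmers_of_sequence(encode_seq(seq), k)}
        assert got == brute_force_canonical_kmers(seq, k)

    def test_canonical_is_min_of_strand_pair(self):
        rng = np.random.default_rng(0)
        for k in (3, 11, 25):
            codes = rng.integers(0, 2 ** (2 * k), size=50).astype(np.uint64)
            for c in canonical(codes, k):
                s = decode_kmer(int(c), k)
                assert s <= revcomp(s)

    def test_reads_kmers_match_sequence_kmers(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 4, size=(20, 51)).astype(np.uint8)
        km, valid = kmers_of_reads(rows, 25)
        assert valid.all()
        for i in range(20):
            seq = "".join("ACGT"[c] for c in rows[i])
            expect = [kmers_of_sequence(encode_seq(seq), 25)]
            assert np.array_equal(np.sort(km[i]), np.sort(expect[0]))

    def test_invalid_bases_invalidate_spanning_windows(self):
        rows = encode_seq("ACGTNACGTACGT")[None, :]
        km, valid = kmers_of_reads(rows, 3)
        # windows overlapping position 4 (N) are invalid
        assert list(~valid[0]) == [False, False, True, True, True] + [False] * 6

    def test_numba_kernels_match_numpy_fallback(self):
        from xenosplit import _kernels

        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba not installed; fallback is the only path")
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 4, size=(5000, 51)).astype(np.uint8)
        rows[rng.random(rows.shape) < 0.01] = 255
        big_km, big_valid = kmers_of_reads(rows, 25)  # numba path (large)
        small = [kmers_of_reads(rows[i : i + 1], 25) for i in range(0, 100)]
        for i, (km, valid) in enumerate(small):
            assert np.array_equal(valid[0], big_valid[i])
            assert np.array_equal(km[0][valid[0]], big_km[i][big_valid[i]])


class TestBuildIndex:
    def test_identical_references_all_both(self):
        idx = build_index(["ACGTACGT"], ["ACGTACGT"], k=5)
        assert idx.graft_only.size == 0 and idx.host_only.size == 0
        assert idx.both_sets.size > 0

    def test_disjoint_references_empty_both(self):
        idx = build_index(["AAAAA"], ["CCCCC"], k=5)
        assert idx.both_sets.size == 0
        assert idx.graft_only.size == 1 and idx.host_only.size == 1

    def test_toy_index_matches_exhaustive_enumeration(self, toy_index):
        graft = brute_force_canonical_kmers("ACGTA", 3)
        host = brute_force_canonical_kmers("TTTTT", 3)
        got_graft = {decode_kmer(int(c), 3) for c in toy_index.graft_only}
        got_host = {decode_kmer(int(c), 3) for c in toy_index.host_only}
        # canonical forms: ACG and CGT collapse to ACG; GTA < its revcomp TAC
        assert got_graft == graft - host == {"ACG", "GTA"}
        assert got_host == host - graft == {"AAA"}
        assert toy_index.both_sets.size == 0

    def test_partition_is_disjoint_and_complete(self, small_cohort):
        idx = small_cohort["index"]
        union = np.concatenate([idx.graft_only, idx.host_only, idx.both_sets])
        assert np.unique(union).size == union.size
        graft_ref = np.unique(
            np.concatenate(
                [kmers_of_sequence(encode_seq(g.graft_seq), idx.k)
                 for g in small_cohort["genes"]]
            )
        )
        assert np.isin(graft_ref, union).all()

    def test_k_validation(self):
        with pytest.raises(ValueError):
            build_index(["ACGTACGT"], ["ACGTACGT"], k=4)
        with pytest.raises(ValueError):
            build_index(["ACG"], ["ACGTT"], k=5)

    def test_round_trip_serialization(self, small_cohort, tmp_path):
        idx = small_cohort["index"]
        path = tmp_path / "index.npz"
        idx.save(path)
        back = KmerIndex.load(path)
        assert back.k == idx.k
        for attr in ("graft_only", "host_only", "both_sets"):
            assert np.array_equal(getattr(back, attr), getattr(idx, attr))
        reads = small_cohort["reads"]["P01_pdx"]
        a = classify_batch(idx, reads.mate1[:500], reads.mate2[:500])
        b = classify_batch(back, reads.mate1[:500], reads.mate2[:500])
        assert np.array_equal(a.category_codes, b.category_codes)


class TestClassifyRead:
    def test_hand_enumerated_graft_read(self, toy_index):
        res = classify_read("CGTA", toy_index)
        assert res.category == "graft"
        assert res.counts == (2, 0, 0, 0)

    def test_hand_enumerated_host_read(self, toy_index):
        res = classify_read("TTTT", toy_index)
        assert res.category == "host"
        assert res.counts == (0, 2, 0, 0)

    def test_hand_enumerated_ambiguous_read(self, toy_index):
        res = classify_read("ACGTTT", toy_index)
        assert res.category == "ambiguous"
        assert res.counts[0] > 0 and res.counts[1] > 0

    def test_both_category(self):
        idx = build_index(["ACGTACGTAC"], ["ACGTACGTAC"], k=5)
        assert classify_read("ACGTACG", idx).category == "both"

    def test_neither_category(self, toy_index):
        # GGG/GGC windows absent from both toy references
        assert classify_read("GGGC", toy_index).category == "neither"

    def test_short_mate_error_names_read(self, toy_index):
        with pytest.raises(ValueError, match="read_7"):
            classify_read(("read_7", "AC", None), toy_index)

    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_every_read_gets_exactly_one_category(self, toy_index, seq):
        res = classify_read(seq, toy_index)
        assert res.category in CATEGORIES
        h, m, b, u = res.counts
        assert h + m + b + u == len(seq) - 3 + 1

    def test_pair_pooling_counts_both_mates(self, toy_index):
        res = classify_read(("r", "CGTA", "TTTT"), toy_index)
        # graft evidence from mate1, host evidence from mate2
        assert res.category == "ambiguous"
        assert sum(res.counts) == 4


class TestSelectHuman:
    def test_all_host_reads_yield_empty_set(self):
        cls = [ReadClassification(f"r{i}", "host", (0, 2, 0, 0)) for i in range(5)]
        ids, report = select_human(cls)
        assert ids == set()
        assert report["tallies"]["host"] == 5

    def test_category_definition_of_retained_set(self):
        spec = {"graft": 3, "both": 2, "ambiguous": 1, "host": 4, "neither": 1}
        cls, n = [], 0
        for cat, count in spec.items():
            for _ in range(count):
                cls.append(ReadClassification(f"r{n}", cat, (0, 0, 0, 0)))
                n += 1
        ids, report = select_human(cls)
        assert len(ids) == 6
        assert report["total"] == 11

    def test_error_free_graft_reads_fully_retained(self, small_cohort):
        """Retention theorem at small scale: no graft k-mer can be host-only."""
        genes = small_cohort["genes"]
        design = CohortDesign(
            n_pairs=2, fragments_per_sample=2000, base_error_rate=0.0, seed=13
        )
        counts = simulate_counts(genes, design)
        idx = small_cohort["index"]
        for reads in simulate_reads(genes, design, counts):
            res = classify_batch(idx, reads.mate1, reads.mate2)
            graft = reads.true_species == 0
            assert res.retained_mask()[graft].all()
            # and no graft read is ever categorised as host
            assert not (res.categories[graft] == "host").any()


class TestLeakage:
    def test_host_leakage_decreases_with_divergence(self, small_cohort):
        genes = small_cohort["genes"]
        idx = small_cohort["index"]
        design = CohortDesign(
            n_pairs=2, fragments_per_sample=20000, base_error_rate=0.0, seed=17
        )
        counts = simulate_counts(genes, design)
        cons = np.array([g.conservation for g in genes])
        stroma_cons = [g.conservation for g in genes if g.compartment == "stroma"]
        split = float(np.median(stroma_cons))
        retained = np.zeros(2)
        totals = np.zeros(2)
        for reads in simulate_reads(genes, design, counts, samples=["P01_pdx", "P02_pdx"]):
            res = classify_batch(idx, reads.mate1, reads.mate2)
            host = reads.true_species == 1
            hc = cons[reads.true_gene[host]]
            hr = res.retained_mask()[host]
            lowbin = hc < split
            retained[0] += hr[lowbin].sum()
            totals[0] += lowbin.sum()
            retained[1] += hr[~lowbin].sum()
            totals[1] += (~lowbin).sum()
        assert totals.min() > 0
        low_frac = retained[0] / totals[0]
        high_frac = retained[1] / totals[1]
        assert low_frac <= high_frac
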