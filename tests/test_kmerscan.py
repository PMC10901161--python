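"""Scanner correctness: enumeration examples, naive-oracle equivalence,
strand invariance and counting laws."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vectorfree._encode import revcomp
from vectorfree.experiments import naive_scan
from vectorfree.kmerscan import (
    build_index,
    canonical,
    read_profile,
    scan_reads,
    write_profile,
)
from vectorfree.simulate import ReadSet, integrate, make_host_genome, make_vector, simulate_reads


def _readset(seqs, length=None):
    length = length or max(len(s) for s in seqs)
    return ReadSet([(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)], length)


class TestBuildIndex:
    def test_linear_enumeration(self):
        idx = build_index("ACGTAC", 4, topology="linear")
        assert idx.kmer_to_positions == {"ACGT": [1], "CGTA": [2], "GTAC": [3]}
        assert idx.n_positions == 3

    def test_circular_wraparound(self):
        # manual enumeration: positions 4..6 carry the wrap-around k-mers
        # TACA, ACAC(G->canonical ACAC? no: window ACAC), CACG
        idx = build_index("ACGTAC", 4, topology="circular")
        assert idx.n_positions == 6
        assert idx.kmer_to_positions["TACA"] == [4]
        assert idx.kmer_to_positions["ACAC"] == [5]
        assert idx.kmer_to_positions["CACG"] == [6]

    def test_palindromic_canonical_key(self):
        assert canonical("ACGT") == canonical("ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA")))
        idx = build_index("AACGTA", 4, topology="linear")
        # ACGT at position 2 is its own reverse complement
        assert 2 in idx.kmer_to_positions["ACGT"]

    def test_duplicate_kmers_share_positions(self):
        idx = build_index("ACGTACGT", 4, topology="linear")
        assert idx.kmer_to_positions["ACGT"] == [1, 5]

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            build_index("ACGTAC", 3)
        with pytest.raises(ValueError):
            build_index("ACGTAC", 64)


class TestScanReads:
    def test_single_read_example(self):
        idx = build_index("ACGTAC", 4, topology="linear")
        prof = scan_reads(_readset(["ACGTA"]), idx)
        assert prof.counts.tolist() == [1, 1, 0]
        assert prof.library_size == 1

    def test_reverse_complement_read(self):
        idx = build_index("ACGTAC", 4, topology="linear")
        prof = scan_reads(_readset([revcomp("CGTAC")]), idx)
        assert prof.counts.tolist() == [0, 1, 1]

    def test_disjoint_kmer_sets(self, vector):
        other = make_host_genome(2000, 0.5, seed=99)
        reads = simulate_reads(other, 5, 50, seed=1)
        prof = scan_reads(reads, build_index(vector, 20))
        assert prof.counts.sum() == 0

    def test_read_increments_position_once(self):
        idx = build_index("ACGTACGT", 4, topology="linear")
        # the read contains ACGT twice but counts once per position
        prof = scan_reads(_readset(["ACGTACGT"]), idx)
        assert prof.counts.max() == 1

    def test_short_reads_count_in_library_size_only(self):
        idx = build_index("ACGTAC", 5, topology="linear")
        prof = scan_reads(_readset(["ACG", "ACGTA"], length=5), idx)
        assert prof.library_size == 2
        assert prof.counts.tolist() == [1, 0]

    def test_empty_read_set_warns(self):
        idx = build_index("ACGTAC", 4, topology="linear")
        with pytest.warns(UserWarning):
            prof = scan_reads(ReadSet([], 100), idx)
        assert prof.library_size == 0
        assert prof.counts.sum() == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [20, 25])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_substring_scan(self, k, seed):
        vector = make_vector(500, 500, seed=3)
        host = make_host_genome(2000, 0.5, seed=4)
        genome, _ = integrate(host, vector, (200, 900), 1000)
        reads = simulate_reads(genome, 3, 60, error_rate=0.01, seed=seed)
        idx = build_index(vector, k)
        prof = scan_reads(reads, idx)
        oracle = naive_scan(reads, vector.sequence, k, "circular")
        np.testing.assert_array_equal(prof.counts, oracle)

    def test_generic_path_matches_packed(self, small_vector):
        # mixed-length reads force the per-read fallback; same answer
        host = make_host_genome(1500, 0.5, seed=5)
        genome, _ = integrate(host, small_vector, (1, 400), 700)
        reads = simulate_reads(genome, 4, 50, seed=6)
        idx = build_index(small_vector, 20)
        packed = scan_reads(reads, idx).counts
        ragged = ReadSet(reads.reads + [("tail", "ACGT", "IIII")], 50)
        generic = scan_reads(ragged, idx).counts
        np.testing.assert_array_equal(packed, generic)


class TestCountingLaws:
    def test_strand_invariance(self, small_vector):
        host = make_host_genome(1500, 0.5, seed=5)
        genome, _ = integrate(host, small_vector, (1, 500), 700)
        reads = simulate_reads(genome, 5, 50, seed=7)
        flipped = _readset([revcomp(s) for s in reads.sequences()], 50)
        idx = build_index(small_vector, 20)
        np.testing.assert_array_equal(
            scan_reads(reads, idx).counts, scan_reads(flipped, idx).counts
        )

    def test_duplication_doubles_counts(self, small_vector):
        host = make_host_genome(1500, 0.5, seed=5)
        genome, _ = integrate(host, small_vector, (1, 500), 700)
        reads = simulate_reads(genome, 5, 50, seed=8)
        doubled = ReadSet(reads.reads + reads.reads, 50)
        idx = build_index(small_vector, 20)
        np.testing.assert_array_equal(
            2 * scan_reads(reads, idx).counts, scan_reads(doubled, idx).counts
        )

    def test_k_nesting_error_free(self, vector):
        host = make_host_genome(5000, 0.5, seed=9)
        genome, _ = integrate(host, vector, (1, 2000), 2500)
        reads = simulate_reads(genome, 10, 100, error_rate=0.0, seed=10)
        hits20 = scan_reads(reads, build_index(vector, 20)).counts > 0
        hits25 = scan_reads(reads, build_index(vector, 25)).counts > 0
        assert not np.any(hits25 & ~hits20)


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=12), min_size=1, max_size=8))
def test_property_profile_matches_oracle_on_random_reads(seqs):
    vector_seq = "ACGTTGCAAGGTTCACGGTT"
    reads = ReadSet([(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)], 12)
    idx = build_index(vector_seq, 6, topology="circular")
    prof = scan_reads(reads, idx)
    np.testing.assert_array_equal(prof.counts, naive_scan(reads, vector_seq, 6))


def test_profile_io_roundtrip(tmp_path, small_vector):
    host = make_host_genome(1500, 0.5, seed=5)
    genome, _ = integrate(host, small_vector, (1, 300), 700)
    reads = simulate_reads(genome, 3, 50, seed=11)
    prof = scan_reads(reads, build_index(small_vector, 20))
    write_profile(tmp_path / "p.tsv", prof)
    back = read_profile(tmp_path / "p.tsv")
    np.testing.assert_array_equal(back.counts, prof.counts)
    assert back.library_size == prof.library_size
    assert back.k == prof.k
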