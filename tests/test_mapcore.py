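"""Scoring engine: counting, alignment, both methods, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from temap import (
    Genome,
    MapParams,
    ReadPair,
    align_all_pe,
    align_all_se,
    count_kmers,
    extract_pair,
    mappability_track,
    oracle_score,
    revcomp,
)
from tests.conftest import random_genome, random_seq


class TestKmerCounting:
    def test_palindromic_kmer_counts_both_strands(self):
        # ACGT at (0,+),(4,+),(0,-),(4,-): palindrome doubles up
        table = count_kmers(Genome({"chr1": "ACGTACGT"}), 4)
        assert table.count("ACGT") == 4

    def test_nonpalindromic_forward_only(self):
        table = count_kmers(Genome({"chr1": "AAAA"}), 4)
        assert table.count("AAAA") == 1

    def test_n_windows_skipped(self):
        table = count_kmers(Genome({"chr1": "ACGNACG"}), 3)
        assert table.count("ACG") == 2  # the two N-free copies only
        assert all("N" not in k for k in table.kmers())

    def test_k_larger_than_genome_empty(self):
        assert len(count_kmers(Genome({"chr1": "ACGT"}), 10)) == 0


class TestExtractPair:
    def test_gap_discarded_and_mate_reversed(self):
        seq = random_seq(242, 1)
        g = Genome({"chr1": seq})
        params = MapParams(r=76, m=3, mode="paired", L=242)
        assert params.gap == 90
        pair = extract_pair(g, "chr1", 0, params)
        assert pair.read1 == seq[:76]
        assert pair.read2 == revcomp(seq[242 - 76 :])

    def test_r50_l200_geometry(self):
        seq = random_seq(200, 2)
        g = Genome({"chr1": seq})
        params = MapParams(r=50, m=0, mode="paired", L=200)
        assert params.gap == 100
        pair = extract_pair(g, "chr1", 0, params)
        assert pair.read2 == revcomp(seq[150:])

    def test_out_of_range_and_n_give_undefined(self):
        g = Genome({"chr1": random_seq(100, 3) + "N" + random_seq(99, 4)})
        params = MapParams(r=20, m=0, mode="paired", L=60)
        assert extract_pair(g, "chr1", 150, params) is None  # runs off the end
        assert extract_pair(g, "chr1", 90, params) is None  # window contains N


class TestAlignAllSE:
    def test_unique_window_single_placement(self):
        g = random_genome(10, 500)
        read = g["chr1"][100:120]
        placements = align_all_se(read, g, 0)
        assert len(placements) == 1
        assert (placements[0].s1, placements[0].strand) == (100, "+")

    def test_two_diverged_copies_within_allowance(self):
        core = random_seq(30, 11)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = flip[core[0]] + core[1:15] + flip[core[15]] + core[16:]
        assert sum(a != b for a, b in zip(core, mutated)) == 2
        g = Genome({"chr1": random_seq(50, 12) + core + random_seq(50, 13) + mutated})
        placements = align_all_se(core, g, 3)
        assert len(placements) >= 2
        starts = {p.s1 for p in placements if p.strand == "+"}
        assert {50, 130} <= starts  # spacer(50) + core(30) + spacer(50)

    def test_matches_brute_force_on_random_genome(self):
        g = random_genome(14, 2000)
        seq = g["chr1"]
        rng = np.random.default_rng(15)
        for pos in rng.integers(0, 2000 - 15, 20):
            read = seq[pos : pos + 15]
            got = {(p.s1, p.strand) for p in align_all_se(read, g, 2)}
            expect = set()
            for q in range(2000 - 15 + 1):
                win = seq[q : q + 15]
                if sum(a != b for a, b in zip(read, win)) <= 2:
                    expect.add((q, "+"))
                if sum(a != b for a, b in zip(revcomp(read), win)) <= 2:
                    expect.add((q, "-"))
            assert got == expect


class TestAlignAllPE:
    def test_unique_fragment_fixed_insert_self_only(self):
        g = random_genome(20, 800)
        params = MapParams(r=20, m=0, mode="paired", L=60, insert_min=60, insert_max=60)
        pair = extract_pair(g, "chr1", 100, params)
        placements = align_all_pe(pair, g, params)
        assert len(placements) == 1
        assert placements[0].s1 == 100 and placements[0].fragment_len == 60

    def test_tandem_repeat_same_start_multiple_inserts(self, tandem_genome):
        g = tandem_genome["genome"]
        params = MapParams(r=20, m=0, mode="paired", L=60, insert_min=50, insert_max=70)
        p = tandem_genome["tandem_start"] - 20  # read1 unique, mate in repeat
        pair = extract_pair(g, "chr1", p, params)
        placements = align_all_pe(pair, g, params)
        same_start = [pl for pl in placements if pl.s1 == p and pl.strand == "+"]
        lens = {pl.fragment_len for pl in same_start}
        assert lens == {50, 60, 70}  # period-10 repeat within +-10 slack

    def test_two_exact_copies_two_placements(self):
        block = random_seq(80, 21)
        g = Genome({"chr1": random_seq(60, 22) + block + random_seq(60, 23) + block})
        params = MapParams(r=20, m=0, mode="paired", L=60, insert_min=60, insert_max=60)
        pair = extract_pair(g, "chr1", 60, params)
        placements = align_all_pe(pair, g, params)
        assert len(placements) == 2
        assert {pl.s1 for pl in placements} == {60, 200}


class TestMappabilityTrack:
    def test_worked_example_five_exact_copies(self, five_copy_genome):
        g, w, starts = five_copy_genome
        for method in ("method1", "method2"):
            params = MapParams(r=len(w), m=1, mode="single", method=method)
            arr = mappability_track(g, params)["chr1"]
            for s in starts:
                assert arr[s] == pytest.approx(1 / 5)

    def test_worked_example_counts_three_plus_one(self, two_kmer_genome):
        g, f, w, pos = two_kmer_genome
        table = count_kmers(g, len(f))
        assert (table.count(f), table.count(w)) == (1, 3)
        for method in ("method1", "method2"):
            params = MapParams(r=len(f), m=1, mode="single", method=method)
            arr = mappability_track(g, params)["chr1"]
            assert arr[pos] == pytest.approx(1 / 4)

    def test_unique_genome_scores_one_everywhere(self):
        g = random_genome(30, 600)
        arr = mappability_track(g, MapParams(r=25, m=0, mode="single"))["chr1"]
        defined = arr[~np.isnan(arr)]
        assert (defined == 1.0).all()

    def test_n_and_edge_positions_undefined(self):
        g = Genome({"chr1": random_seq(50, 31) + "N" + random_seq(50, 32)})
        arr = mappability_track(g, MapParams(r=20, m=0, mode="single"))["chr1"]
        assert np.isnan(arr[40])  # window covers the N
        assert np.isnan(arr[101 - 10])  # window runs off the end
        assert not np.isnan(arr[10])

    def test_scores_are_reciprocal_integers(self):
        g = random_genome(33, 1500)
        seq = g["chr1"]
        g = Genome({"chr1": seq[:1200] + seq[300:600]})  # planted duplication
        for params in (
            MapParams(r=18, m=1, mode="single"),
            MapParams(r=18, m=1, mode="paired", L=50, insert_min=40, insert_max=60),
        ):
            arr = mappability_track(g, params)["chr1"]
            defined = arr[~np.isnan(arr)]
            inv = 1.0 / defined
            np.testing.assert_allclose(inv, np.round(inv), atol=1e-9)
            assert (defined <= 1.0).all() and (defined > 0).all()

    def test_count_table_k_mismatch_error(self):
        g = random_genome(34, 300)
        table = count_kmers(g, 15)
        with pytest.raises(ValueError):
            mappability_track(g, MapParams(r=20, m=0, mode="single"), table)

    def test_read_length_monotonicity(self):
        seq = random_seq(900, 35)
        g = Genome({"chr1": seq + seq[200:400] + seq[600:900]})
        t1 = mappability_track(g, MapParams(r=20, m=2, mode="single"))["chr1"]
        t2 = mappability_track(g, MapParams(r=30, m=2, mode="single"))["chr1"]
        both = ~np.isnan(t1) & ~np.isnan(t2)
        assert both.any()
        assert (t2[both] >= t1[both]).all()

    def test_pe_below_se_only_with_insert_slack(self, tandem_genome):
        g = tandem_genome["genome"]
        se = mappability_track(g, MapParams(r=20, m=0, mode="single"))["chr1"]
        slack = MapParams(r=20, m=0, mode="paired", L=60, insert_min=50, insert_max=70)
        pe = mappability_track(g, slack)["chr1"]
        p = tandem_genome["tandem_start"] - 20
        assert pe[p] < se[p] == 1.0
        fixed = MapParams(r=20, m=0, mode="paired", L=60, insert_min=60, insert_max=60)
        pe_fixed = mappability_track(g, fixed)["chr1"]
        both = ~np.isnan(pe_fixed) & ~np.isnan(se)
        assert (pe_fixed[both] >= se[both]).all()


class TestOracleAgreement:
    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_se_indexed_equals_naive_scan(self, m):
        g = random_genome(40, 2000)
        seq = g["chr1"]
        g = Genome({"chr1": seq[:1700] + seq[400:700]})
        params = MapParams(r=15, m=m, mode="single", method="method2")
        arr = mappability_track(g, params)["chr1"]
        rng = np.random.default_rng(41 + m)
        for pos in rng.integers(0, len(g["chr1"]) - 15, 40):
            o = oracle_score(g, "chr1", int(pos), params)
            assert math.isclose(arr[pos], o)

    @pytest.mark.parametrize("method", ["method1", "method2"])
    def test_pe_indexed_equals_naive_scan(self, method):
        g = random_genome(42, 1500)
        seq = g["chr1"]
        g = Genome({"chr1": seq[:1200] + seq[300:600]})
        params = MapParams(
            r=15, m=1, mode="paired", L=50, insert_min=40, insert_max=60, method=method
        )
        arr = mappability_track(g, params)["chr1"]
        rng = np.random.default_rng(43)
        for pos in rng.integers(0, len(g["chr1"]) - 50, 25):
            o = oracle_score(g, "chr1", int(pos), params)
            assert math.isclose(arr[pos], o)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    m=st.integers(0, 2),
    dup=st.booleans(),
)
def test_property_se_methods_identical(seed, m, dup):
    """Single-end method 1 and method 2 agree exactly on arbitrary genomes."""
    base = random_seq(400, seed)
    seq = base + base[100:220] if dup else base
    g = Genome({"chr1": seq})
    p1 = MapParams(r=12, m=m, mode="single", method="method1")
    p2 = MapParams(r=12, m=m, mode="single", method="method2")
    a1 = mappability_track(g, p1)["chr1"]
    a2 = mappability_track(g, p2)["chr1"]
    np.testing.assert_array_equal(a1, a2)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_property_score_one_iff_unique_placement(seed):
    g = random_genome(seed, 400)
    params = MapParams(r=14, m=1, mode="single", method="method2")
    arr = mappability_track(g, params)["chr1"]
    rng = np.random.default_rng(seed)
    for pos in rng.integers(0, 400 - 14, 8):
        read = g["chr1"][pos : pos + 14]
        n_pl = len(align_all_se(read, g, 1))
        assert math.isclose(arr[pos], 1.0 / n_pl)
        assert (arr[pos] == 1.0) == (n_pl == 1)
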