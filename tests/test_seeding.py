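"""Minimizer extraction, index construction, anchor collection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import py_minimizers
from seedchain import (
    IndexBuildError,
    MapParams,
    build_index,
    collect_anchors,
    extract_minimizers,
)
from seedchain.simulate import random_reference, revcomp

dna_st = st.text(alphabet="ACGTN", max_size=200)


class TestExtractMinimizers:
    def test_too_short_sequence(self):
        assert extract_minimizers("ACGT", 5, 3) == []

    def test_homopolymer_tie_break(self):
        # every window holds the same canonical k-mer; leftmost-minimum
        # tie-break selects each window's first position exactly once
        out = extract_minimizers("AAAAAA", 3, 2)
        assert [p for _, p, _ in out] == [2, 3, 4]
        assert len({h for h, _, _ in out}) == 1

    def test_window_of_one_reports_every_kmer(self):
        seq = "ACGGTACCATGGAT"
        out = extract_minimizers(seq, 5, 1)
        assert [p for _, p, _ in out] == list(range(4, len(seq)))

    def test_ambiguous_bases_skipped(self):
        out = extract_minimizers("ACGTNACGTT", 3, 2)
        assert all(p not in (4, 5, 6) for _, p, _ in out)  # k-mers covering N

    @given(dna_st, st.integers(2, 7), st.integers(1, 6))
    def test_matches_bruteforce_window_scan(self, seq, k, wmin):
        assert extract_minimizers(seq, k, wmin) == py_minimizers(seq, k, wmin)

    def test_matches_bruteforce_on_long_random(self):
        seq = random_reference(3000, 9)
        for k, wmin in [(15, 10), (11, 5), (21, 11)]:
            assert extract_minimizers(seq, k, wmin) == py_minimizers(seq, k, wmin)

    def test_deterministic(self):
        seq = random_reference(500, 1)
        assert extract_minimizers(seq, 15, 10) == extract_minimizers(seq, 15, 10)


class TestBuildIndex:
    def test_homopolymer_has_single_key(self, params):
        idx = build_index([("r", "A" * 100)], params)
        assert idx.n_keys == 1

    def test_empty_reference_rejected(self, params):
        with pytest.raises(IndexBuildError):
            build_index([], params)
        with pytest.raises(IndexBuildError):
            build_index([("r", "")], params)

    def test_duplicate_record_doubles_postings(self, params):
        seq = random_reference(2000, 2)
        one = build_index([("a", seq)], params)
        two = build_index([("a", seq), ("b", seq)], params)
        assert two.n_postings == 2 * one.n_postings
        h = int(one.hashes[0])
        assert len(two.query(h)[0]) == 2 * len(one.query(h)[0])

    def test_postings_match_direct_extraction(self, params):
        seq = random_reference(10_000, 3)
        idx = build_index([("r", seq)], params)
        direct = extract_minimizers(seq, params.k, params.wmin)
        assert idx.n_postings == len(direct)
        got = sorted(zip(idx.hashes.tolist(), idx.pos.tolist()))
        assert got == sorted((h, p) for h, p, _ in direct)

    def test_absent_hash_yields_empty(self, params):
        idx = build_index([("r", random_reference(2000, 4))], params)
        absent = 0
        while absent in set(idx.hashes.tolist()):
            absent += 1
        assert idx.query(absent)[0].size == 0


class TestCollectAnchors:
    def test_exact_substring_gives_perfect_diagonal(self, params):
        ref = random_reference(20_000, 5)
        read = ref[4000:9000]
        idx = build_index([("r", ref)], params)
        groups = collect_anchors(idx, ("q", read), params)
        fwd = [g for g in groups if g.strand == "+"]
        assert fwd
        g = max(fwd, key=len)
        assert len(set((g.x - g.y).tolist())) == 1
        assert int(g.x[0] - g.y[0]) == 4000

    def test_reverse_complement_read_lands_on_minus_strand(self, params):
        ref = random_reference(20_000, 6)
        read = revcomp(ref[4000:9000])
        idx = build_index([("r", ref)], params)
        groups = collect_anchors(idx, ("q", read), params)
        g = max(groups, key=len)
        assert g.strand == "-"
        # transformed coordinates restore a single diagonal
        assert len(set((g.x - g.y).tolist())) == 1

    def test_no_shared_minimizers(self, params):
        idx = build_index([("r", "A" * 200)], params)
        assert collect_anchors(idx, ("q", "C" * 200), params) == []

    def test_read_shorter_than_k(self, params):
        idx = build_index([("r", random_reference(1000, 7))], params)
        assert collect_anchors(idx, ("q", "ACGT"), params) == []

    def test_groups_sorted_and_uniform(self, params):
        ref = random_reference(30_000, 8)
        read = ref[1000:3000] + revcomp(ref[20_000:22_000])
        idx = build_index([("r", ref)], params)
        for g in collect_anchors(idx, ("q", read), params):
            assert g.is_sorted()
            assert np.all(g.w == params.k)

    def test_max_occ_filters_minimizers(self):
        strict = MapParams(max_occ=0)
        seq = random_reference(2000, 9)
        idx = build_index([("r", seq)], strict)
        assert collect_anchors(idx, ("q", seq[200:1800]), strict) == []
        loose = MapParams()
        idx2 = build_index([("r", seq)], loose)
        assert collect_anchors(idx2, ("q", seq[200:1800]), loose)
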