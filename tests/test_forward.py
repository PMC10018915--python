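"""Forward-transformed chaining: ranges, condensation, equivalence, binning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import anchor_battery, linear_successor_end
from seedchain import (
    Anchor,
    AnchorSet,
    ContractViolationError,
    SuccessorRanges,
    bin_reads,
    chain_dp_backward,
    chain_dp_forward,
    condense,
    sort_anchors,
    successor_range,
    successor_ranges,
)
from seedchain.model import backtrack_path_max, check_v_recurrence
from seedchain.simulate import plant_chains, AnchorSimSpec


def spaced(n, spacing, w=15):
    return sort_anchors([Anchor(w - 1 + i * spacing, w - 1 + i * spacing, w)
                         for i in range(n)])


class TestSuccessorRange:
    def test_single_anchor_empty_range(self, params):
        assert successor_range(spaced(1, 100), 0, params) == 1

    def test_all_within_threshold(self, params):
        # 10 anchors spaced 100: max gap 900 <= 5000
        assert successor_range(spaced(10, 100), 0, params) == 10

    def test_probe_overshoot_then_decrement(self, params):
        # spacing 400: probe delta=16 lands at gap 6400 > 5000,
        # decrement to the last anchor with gap <= 5000 (index 12)
        assert successor_range(spaced(20, 400), 0, params) == 13

    def test_count_cap(self, params):
        n = 6000
        xs = np.arange(n, dtype=np.int64) + 14
        aset = AnchorSet(xs, xs.copy(), np.full(n, 15))
        assert successor_range(aset, 0, params) == 5001

    def test_heuristic_equals_linear_scan_everywhere(self, params):
        for aset in anchor_battery(24, 404, max_n=300):
            ends = successor_ranges(aset, params).end_idx
            for i in range(len(aset)):
                expect = linear_successor_end(aset, i, params)
                assert successor_range(aset, i, params) == expect
                assert ends[i] == expect


class TestCondense:
    def test_all_empty(self):
        assert len(condense(SuccessorRanges(np.array([1, 2, 3])))) == 0

    def test_example(self):
        wl = condense(SuccessorRanges(np.array([2, 2, 5, 4, 5])))
        assert list(wl.indices) == [0, 2]

    def test_ont_like_fraction_is_qualitatively_sparse(self, params):
        # planted chains + genome-scale stray hits: a large fraction of
        # anchors continues no chain, roughly matching long-read practice
        fracs = []
        for seed in range(10):
            aset, _ = plant_chains(AnchorSimSpec(seed=seed))
            wl = condense(successor_ranges(aset, params))
            fracs.append(len(wl) / len(aset))
        assert 0.1 < np.mean(fracs) < 0.6


class TestChainDpForward:
    def test_single_anchor(self, params):
        st = chain_dp_forward(spaced(1, 100), params=params)
        assert list(st.S) == [15] and list(st.P) == [-1] and list(st.V) == [15]

    def test_three_anchor_diagonal(self, params):
        st = chain_dp_forward(spaced(3, 100, w=15), params=params)
        assert list(st.S) == [15, 30, 45]
        assert list(st.P) == [-1, 0, 1]
        assert list(st.V) == [15, 30, 45]

    def test_equivalent_to_backward_on_battery(self, params):
        for i, aset in enumerate(anchor_battery(200, 505, max_n=800)):
            fwd = chain_dp_forward(aset, params=params)
            bwd = chain_dp_backward(aset, params)
            assert fwd == bwd, f"set {i} (n={len(aset)})"

    def test_condensed_workload_is_neutral(self, params):
        for aset in anchor_battery(40, 606, max_n=500):
            ranges = successor_ranges(aset, params)
            full = chain_dp_forward(aset, ranges, params)
            cond = chain_dp_forward(aset, ranges, params,
                                    workload=condense(ranges))
            assert full == cond

    def test_v_equals_max_score_along_backtrack_path(self, params):
        rng = np.random.default_rng(7)
        for aset in anchor_battery(24, 707, max_n=400):
            st = chain_dp_forward(aset, params=params)
            assert check_v_recurrence(st)
            n = len(aset)
            for i in rng.integers(0, n, size=min(20, n)):
                assert st.V[i] == backtrack_path_max(st, int(i))

    def test_inconsistent_ranges_rejected(self, params):
        aset = spaced(3, 100)
        with pytest.raises(ContractViolationError):
            chain_dp_forward(aset, SuccessorRanges(np.array([5, 3, 4])), params)
        with pytest.raises(ContractViolationError):
            chain_dp_forward(aset, SuccessorRanges(np.array([0, 3, 4])), params)


class TestBinReads:
    def test_edge_arithmetic(self):
        batches = bin_reads([("r1", 1500), ("r2", 2500), ("r3", 2600)])
        assert [(b.lo, b.hi, b.read_ids) for b in batches] == [
            (1000, 2000, ["r1"]),
            (2000, 3000, ["r2", "r3"]),
        ]

    def test_long_read_bins_are_wide(self):
        (b,) = bin_reads([("r", 120_000)])
        assert (b.lo, b.hi) == (100_000, 150_000)
        (b,) = bin_reads([("r", 47_000)])
        assert (b.lo, b.hi) == (45_000, 50_000)
        (b,) = bin_reads([("r", 700_000)])
        assert (b.lo, b.hi) == (150_000, None)

    def test_empty_input(self):
        assert bin_reads([]) == []

    @given(st.lists(st.integers(1, 400_000), max_size=80))
    def test_partition_property(self, lengths):
        named = [(f"r{i}", ln) for i, ln in enumerate(lengths)]
        batches = bin_reads(named)
        seen = [r for b in batches for r in b.read_ids]
        assert sorted(seen) == sorted(n for n, _ in named)
        for b in batches:
            for r in b.read_ids:
                ln = dict(named)[r]
                assert b.lo <= ln and (b.hi is None or ln < b.hi)
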