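"""Predecessor-order chaining DP against hand examples and brute force."""

import numpy as np
import pytest

from oracles import anchor_battery, brute_chain
from seedchain import (
    NO_CHAIN,
    Anchor,
    AnchorSet,
    chain_dp_backward,
    pair_score,
    predecessor_range,
    sort_anchors,
)


def diagonal(n, spacing=100, w=15, start=115):
    return sort_anchors(
        [Anchor(start + i * spacing, start + i * spacing, w) for i in range(n)]
    )


class TestPairScore:
    def test_hand_example(self, params):
        # dq=103, dr=100, dd=3: match 15, penalty floor(0.45) + (1>>1) = 0
        sc = pair_score(Anchor(115, 115, 15), Anchor(215, 218, 15), 15.0, params)
        assert sc == 15

    def test_collinear_pair_has_zero_penalty(self, params):
        sc = pair_score(Anchor(115, 115, 15), Anchor(215, 215, 15), 15.0, params)
        assert sc == 15  # dd = 0 -> gamma(0) = 0, match = span

    @pytest.mark.parametrize(
        "aj",
        [
            Anchor(215, 100, 15),    # dq negative
            Anchor(215, 115, 15),    # dq zero
            Anchor(115, 218, 15),    # dr zero
            Anchor(100, 218, 15),    # dr negative
            Anchor(9000, 9000, 15),  # both gaps beyond max_dist
        ],
    )
    def test_filters_yield_no_chain(self, params, aj):
        assert pair_score(Anchor(115, 115, 15), aj, 15.0, params) is NO_CHAIN

    def test_bandwidth_filter(self, params):
        # dr=100, dq=700: dd=600 > bandwidth 500
        aj = Anchor(215, 815, 15)
        assert pair_score(Anchor(115, 115, 15), aj, 15.0, params) is NO_CHAIN

    def test_negative_scores_representable(self, params):
        # big gap difference within bandwidth: penalty exceeds match
        sc = pair_score(Anchor(115, 115, 15), Anchor(615, 1015, 15), 15.0, params)
        assert sc is not NO_CHAIN and sc < 0


class TestPredecessorRange:
    def test_first_anchor_empty_range(self, params):
        assert predecessor_range(diagonal(3), 0, params) == 0

    def test_gap_beyond_threshold_excludes_all(self, params):
        aset = sort_anchors([Anchor(14, 14, 15), Anchor(6014, 6014, 15)])
        assert predecessor_range(aset, 1, params) == 1

    def test_count_cap_at_max_range(self, params):
        n = 6000
        xs = np.arange(n) + 14
        aset = AnchorSet(xs, xs.copy(), np.full(n, 15))
        assert predecessor_range(aset, 5999, params) == 999


class TestChainDpBackward:
    def test_single_anchor(self, params):
        st = chain_dp_backward(diagonal(1), params)
        assert list(st.S) == [15] and list(st.P) == [-1] and list(st.V) == [15]

    def test_empty_set(self, params):
        st = chain_dp_backward(sort_anchors([]), params)
        assert len(st) == 0

    def test_three_anchor_diagonal(self, params):
        st = chain_dp_backward(diagonal(3), params)
        assert list(st.S) == [15, 30, 45]
        assert list(st.P) == [-1, 0, 1]
        assert list(st.V) == [15, 30, 45]

    def test_matches_bruteforce_on_random_sets(self, params):
        for i, aset in enumerate(anchor_battery(24, 202, max_n=250)):
            S, P, V = brute_chain(aset, params)
            st = chain_dp_backward(aset, params)
            assert np.array_equal(st.S, S), f"S mismatch on set {i}"
            assert np.array_equal(st.P, P), f"P mismatch on set {i}"
            assert np.array_equal(st.V, V), f"V mismatch on set {i}"


def skip_fixture():
    """Anchor set where the scan-break heuristic provably misses a chain.

    30 low-span decoys sit immediately before the final anchor; they are
    chainable to it but score poorly and cannot chain each other (their
    query coordinates run backwards).  The one good predecessor lies
    beyond them, so a finite scan break stops before reaching it.
    """
    anchors = [Anchor(30, 30, 15)]
    for t in range(30):
        anchors.append(Anchor(1000 + t, 500 - t, 1))
    anchors.append(Anchor(1030, 600, 15))
    return sort_anchors(anchors)


class TestMaxSkipHeuristic:
    def test_dominance_on_battery(self, params):
        finite = params.replace(max_skip=25)
        for aset in anchor_battery(20, 303, max_n=400):
            s_inf = chain_dp_backward(aset, params).S
            s_fin = chain_dp_backward(aset, finite).S
            assert np.all(s_fin <= s_inf)

    def test_strict_loss_exhibited(self, params):
        aset = skip_fixture()
        s_inf = chain_dp_backward(aset, params)
        s_fin = chain_dp_backward(aset, params.replace(max_skip=25))
        assert np.all(s_fin.S <= s_inf.S)
        assert s_fin.S[-1] < s_inf.S[-1]
        # unbounded run chains the distant good predecessor
        assert s_inf.P[-1] == 0
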