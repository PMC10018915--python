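"""Classic predecessor-order chaining DP (the normative oracle).

This is the sequential formulation used by long-read mappers: anchors are
processed in sort order and each anchor j scans its predecessors
backwards, keeping the best chain score.  With the scan-break heuristic
disabled (``max_skip=None``) the result is the exact DP optimum under the
nearest-predecessor tie-break, which is the contract the forward-transformed
engine must reproduce bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .model import Anchor, AnchorSet, ChainState, MapParams

__all__ = ["NO_CHAIN", "pair_score", "predecessor_range", "chain_dp_backward"]

#: Out-of-band signal returned by :func:`pair_score` when a pair fails a
#: filter.  Deliberately not an integer so legitimate negative scores stay
#: representable.
NO_CHAIN = None


def pair_score(ai: Anchor, aj: Anchor, avg_span: float, params: MapParams):
    """Score contribution of chaining predecessor ``ai`` to successor ``aj``.

    Returns ``match - penalty`` with ``match = min(dq, dr, w_j)`` and
    ``penalty = floor(0.01 * avg_span * dd) + (ilog2(dd) >> 1)`` where
    ``dq``/``dr`` are the query/reference end-coordinate gaps and
    ``dd = |dq - dr|``; returns :data:`NO_CHAIN` when the pair fails a gap
    or bandwidth filter (dr <= 0, dq <= 0, dq > max_dist_y,
    dr > max_dist_x, or dd > bandwidth).
    """
    sc = _kernels.pair_score_kernel(
        ai.x, ai.y, aj.x, aj.y, aj.w, avg_span,
        params.max_dist_x, params.max_dist_y, params.bandwidth,
    )
    return NO_CHAIN if sc == _kernels.NO_CHAIN_SENTINEL else int(sc)


def predecessor_range(anchors: AnchorSet, j: int, params: MapParams) -> int:
    """Start index of anchor j's predecessor range.

    The smallest st with x_j - x_st <= max_dist_x, additionally bounded so
    that at most ``max_range`` predecessors are examined.
    """
    if not 0 <= j < len(anchors):
        raise IndexError(j)
    st = int(np.searchsorted(anchors.x, anchors.x[j] - params.max_dist_x, "left"))
    return max(st, j - params.max_range)


def chain_dp_backward(anchors: AnchorSet, params: MapParams) -> ChainState:
    """Run the predecessor-order chaining DP over one sorted AnchorSet.

    ``params.max_skip`` finite enables the early-exit speed heuristic
    (the scan over predecessors stops after that many consecutive
    non-improving candidates); ``None`` disables it, making the DP exact.
    """
    n = len(anchors)
    if n == 0:
        e = np.empty(0, np.int64)
        return ChainState(e.copy(), e.copy(), e.copy())
    max_skip = -1 if params.max_skip is None else int(params.max_skip)
    S, P, V = _kernels.chain_backward_kernel(
        anchors.x, anchors.y, anchors.w, anchors.avg_span,
        params.max_dist_x, params.max_dist_y, params.bandwidth,
        params.max_range, max_skip,
    )
    return ChainState(S, P, V)
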