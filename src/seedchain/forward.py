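"""Forward-transformed chaining: successor ranges, condensed workload, push DP.

The forward transform re-orders the chaining loops so every anchor pushes
candidate scores to the successors in its range instead of pulling from
predecessors; all pushes from one source are independent, which is what
makes the inner loop parallelisable.  Three pieces realise it here:

* :func:`successor_range` / :func:`successor_ranges` — per-anchor successor
  range, computed with a probe-delta speed heuristic that exploits how
  heavily ranges skew small (most anchors have an empty or tiny range);
* :func:`condense` — the condensed workload vector: indices of anchors with
  non-empty ranges, so compute never idles on zero-work anchors;
* :func:`chain_dp_forward` — the push-order DP itself.

Tie-break note.  The push update accepts ``s >= S[j]`` except the tie
``s == S[j] == w_j``, uniformly for every successor including the
immediate neighbour ``j = i+1``.  Processing sources in ascending order,
this makes the nearest source win score ties — exactly the semantics of
the backward scan (descending, strict improvement), which is the
normative contract.  A strictly-greater test for the immediate neighbour
alone would let a farther anchor keep a tie against it and break
bit-equality on constructible inputs, so it is not used.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import ContractViolationError
from .model import AnchorSet, ChainState, MapParams

__all__ = [
    "SuccessorRanges",
    "CondensedWorkload",
    "successor_range",
    "successor_ranges",
    "condense",
    "chain_dp_forward",
    "ReadBatch",
    "default_bin_edges",
    "bin_reads",
]


@dataclasses.dataclass
class SuccessorRanges:
    """Per-anchor exclusive upper successor index.

    Anchors ``i+1 .. end_idx[i]-1`` are candidate successors of ``i``;
    ``end_idx[i] == i+1`` means the range is empty.
    """

    end_idx: np.ndarray

    def __post_init__(self) -> None:
        self.end_idx = np.asarray(self.end_idx, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.end_idx.size)

    def validate(self, n: int, params: MapParams) -> None:
        if self.end_idx.size != n:
            raise ContractViolationError(
                f"ranges cover {self.end_idx.size} anchors, set has {n}"
            )
        idx = np.arange(n, dtype=np.int64)
        if np.any(self.end_idx < idx + 1) or np.any(self.end_idx > n):
            raise ContractViolationError("successor range end outside [i+1, n]")
        if np.any(self.end_idx > idx + 1 + params.max_range):
            raise ContractViolationError("successor range exceeds max_range cap")


@dataclasses.dataclass
class CondensedWorkload:
    """Ascending indices of anchors with a non-empty successor range."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.indices.size)


def successor_range(anchors: AnchorSet, i: int, params: MapParams) -> int:
    """Exclusive end of anchor i's successor range (probe-delta heuristic).

    Equals the linear-scan answer: the largest ``end`` such that every j in
    (i, end) satisfies ``x_j - x_i <= max_dist_x``, capped at
    ``i + 1 + max_range`` and at n.  Probes are tried in ascending order;
    the first out-of-threshold probe (probes beyond the last anchor count
    as out-of-threshold) brackets the boundary, which is then found by
    decrementing.
    """
    n = len(anchors)
    if not 0 <= i < n:
        raise IndexError(i)
    x = anchors.x
    e = i + params.max_range
    for d in params.probe_deltas:
        p = i + d
        if p >= n or x[p] - x[i] > params.max_dist_x:
            e = p
            break
    e = min(e, n - 1)
    while x[e] - x[i] > params.max_dist_x:
        e -= 1
    return e + 1


def successor_ranges(anchors: AnchorSet, params: MapParams) -> SuccessorRanges:
    """Successor ranges for a whole AnchorSet (vectorised kernel)."""
    if len(anchors) == 0:
        return SuccessorRanges(np.empty(0, np.int64))
    deltas = np.asarray(params.probe_deltas, dtype=np.int64)
    end_idx = _kernels.successor_ranges_kernel(
        anchors.x, params.max_dist_x, params.max_range, deltas
    )
    return SuccessorRanges(end_idx)


def condense(ranges: SuccessorRanges) -> CondensedWorkload:
    """Condensed workload vector: anchors whose successor range is non-empty."""
    n = len(ranges)
    idx = np.arange(n, dtype=np.int64)
    return CondensedWorkload(idx[ranges.end_idx > idx + 1])


def chain_dp_forward(
    anchors: AnchorSet,
    ranges: SuccessorRanges | None = None,
    params: MapParams = MapParams(),
    workload: CondensedWorkload | None = None,
) -> ChainState:
    """Run the forward-transformed chaining DP.

    Produces S, P, V bit-identical to
    :func:`seedchain.backward.chain_dp_backward` with unbounded max_skip.
    ``workload`` optionally restricts the score sources to a condensed
    workload vector; because masked-off anchors have empty ranges this
    must not change the result.
    """
    n = len(anchors)
    if n == 0:
        e = np.empty(0, np.int64)
        return ChainState(e.copy(), e.copy(), e.copy())
    if ranges is None:
        ranges = successor_ranges(anchors, params)
    ranges.validate(n, params)
    if workload is None:
        is_source = np.ones(n, np.bool_)
    else:
        is_source = np.zeros(n, np.bool_)
        is_source[workload.indices] = True
    S, P, V = _kernels.chain_forward_kernel(
        anchors.x, anchors.y, anchors.w, ranges.end_idx, is_source,
        anchors.avg_span, params.max_dist_x, params.max_dist_y,
        params.bandwidth,
    )
    return ChainState(S, P, V)


# ---------------------------------------------------------------------------
# Read-length binning (host-side batching policy)


@dataclasses.dataclass
class ReadBatch:
    """Reads of similar length grouped for one dispatch."""

    lo: int
    hi: int | None  # None = open-ended final bin
    read_ids: list

    @property
    def label(self) -> str:
        hi = "inf" if self.hi is None else str(self.hi)
        return f"[{self.lo},{hi})"


def default_bin_edges() -> list[int]:
    """Bin edges: 1 kb steps to 10 kb, 5 kb steps to 50 kb, then 100/150 kb.

    The final bin (>= 150 kb) is open-ended.  Wider bins for long reads
    reflect that reads of very similar length become rare there.
    """
    edges = list(range(0, 10_000, 1_000))
    edges += list(range(10_000, 50_001, 5_000))
    edges += [100_000, 150_000]
    return edges


def bin_reads(
    read_lengths: Sequence[tuple[str, int]],
    edges: Sequence[int] | None = None,
) -> list[ReadBatch]:
    """Partition reads into length bins; batches come out in bin order.

    Every read lands in exactly one bin; reads keep input order within a
    batch.  Empty bins produce no batch.
    """
    if edges is None:
        edges = default_bin_edges()
    edges = sorted(set(edges))
    bounds = list(zip(edges, edges[1:])) + [(edges[-1], None)]
    batches = [ReadBatch(lo, hi, []) for lo, hi in bounds]
    arr = np.asarray(edges, dtype=np.int64)
    for read_id, length in read_lengths:
        if length <= 0:
            raise ValueError(f"read {read_id!r} has non-positive length {length}")
        b = int(np.searchsorted(arr, length, "right")) - 1
        if b < 0:
            b = 0
        batches[b].read_ids.append(read_id)
    return [b for b in batches if b.read_ids]
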