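"""Backtracking, primary/secondary classification and mapping quality.

These are the chaining sub-tasks that stay cheap and sequential: walking
the predecessor array to emit chains (no anchor reused), masking
query-overlapping chains as secondary, and the empirical mapping-quality
score of a primary chain.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .model import AnchorSet, ChainState, MapParams

__all__ = ["Chain", "backtrack", "identify_primary", "mapping_quality"]


@dataclasses.dataclass
class Chain:
    """One backtracked chain: an ascending anchor subset with its intervals.

    Query/reference intervals are 0-based half-open, from
    ``end - span + 1`` of the first anchor to ``end + 1`` of the last.
    ``of_primary`` is set on secondaries to the index (within the returned
    list) of the best-overlapping primary.
    """

    anchor_indices: list[int]
    score: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    rid: int
    strand: str
    is_primary: bool = True
    mapq: int = 0
    read_id: str = ""
    read_length: int = 0
    matched_bases: int = 0
    of_primary: int | None = None


def backtrack(state: ChainState, anchors: AnchorSet, params: MapParams) -> list[Chain]:
    """Emit chains by walking best-predecessor links, never reusing an anchor.

    Anchor indices are visited in descending (S, index) order; from each
    unused index with S >= min_score the walk follows P until it hits a
    used anchor or a chain start.  The chain score is S at the end anchor
    minus S at the truncation point (0 when the walk reached a start),
    floored at 0.  Chains shorter than min_cnt anchors or scoring below
    min_score are dropped, but their anchors stay consumed.
    """
    n = len(anchors)
    if state.S.size != n:
        raise ValueError("state and anchors disagree on size")
    S, P = state.S, state.P
    order = sorted(range(n), key=lambda i: (S[i], i), reverse=True)
    used = np.zeros(n, np.bool_)
    chains: list[Chain] = []
    for start in order:
        if used[start] or S[start] < params.min_score:
            continue
        path: list[int] = []
        i = start
        trunc_score = 0
        while i >= 0:
            if used[i]:
                trunc_score = int(S[i])
                break
            path.append(i)
            used[i] = True
            i = int(P[i])
        score = max(0, int(S[start]) - trunc_score)
        if len(path) < params.min_cnt or score < params.min_score:
            continue
        path.reverse()
        first, last = path[0], path[-1]
        spans = int(anchors.w[path].sum())
        q_start = int(anchors.y[first] - anchors.w[first] + 1)
        q_end = int(anchors.y[last]) + 1
        r_start = int(anchors.x[first] - anchors.w[first] + 1)
        r_end = int(anchors.x[last]) + 1
        chains.append(
            Chain(
                anchor_indices=path,
                score=score,
                q_start=q_start,
                q_end=q_end,
                r_start=r_start,
                r_end=r_end,
                rid=anchors.rid,
                strand=anchors.strand,
                read_id=anchors.read_id,
                read_length=anchors.read_length,
                matched_bases=min(spans, q_end - q_start, r_end - r_start),
            )
        )
    return chains


def _q_overlap(a: Chain, b: Chain) -> int:
    return max(0, min(a.q_end, b.q_end) - max(a.q_start, b.q_start))


def identify_primary(chains: list[Chain], params: MapParams) -> list[Chain]:
    """Classify chains of one read as primary or secondary by query overlap.

    Chains are considered in descending score (stable for ties).  A chain
    is primary iff its query overlap with every higher-scoring primary is
    below ``mask_level`` times its own query length; otherwise it is
    secondary and points at its best-overlapping primary.
    """
    ordered = sorted(chains, key=lambda c: -c.score)
    primaries: list[int] = []
    for ci, ch in enumerate(ordered):
        ch.is_primary = True
        ch.of_primary = None
        best_ov, best_pi = 0, None
        for pi in primaries:
            ov = _q_overlap(ch, ordered[pi])
            if ov >= params.mask_level * (ch.q_end - ch.q_start):
                ch.is_primary = False
            if ov > best_ov:
                best_ov, best_pi = ov, pi
        if ch.is_primary:
            primaries.append(ci)
        else:
            ch.of_primary = best_pi
    return ordered


def mapping_quality(f1: int, f2: int, m: int) -> int:
    """Empirical mapping quality of a primary chain, clamped to [0, 60].

    f1 = primary chain score, f2 = best overlapping secondary's score
    (0 when none), m = anchor count of the primary chain:
    ``mapq = round(40 * (1 - f2/f1) * min(1, m/10) * ln f1)``.
    """
    if f1 <= 0:
        raise ValueError(f"primary score must be positive, got {f1}")
    if not (0 <= f2 <= f1):
        raise ValueError(f"need 0 <= f2 <= f1, got f1={f1} f2={f2}")
    if m < 1:
        raise ValueError(f"anchor count must be >= 1, got {m}")
    raw = 40.0 * (1.0 - f2 / f1) * min(1.0, m / 10.0) * math.log(f1)
    return max(0, min(60, int(raw + 0.5)))


def assign_mapq(ordered: list[Chain]) -> None:
    """Fill mapq in place: primaries scored against their best secondary."""
    for pi, ch in enumerate(ordered):
        if not ch.is_primary:
            ch.mapq = 0
            continue
        f2 = max(
            (s.score for s in ordered if not s.is_primary and s.of_primary == pi),
            default=0,
        )
        ch.mapq = mapping_quality(ch.score, min(f2, ch.score), len(ch.anchor_indices))
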