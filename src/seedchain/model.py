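"""Core data model for anchor chaining.

An *anchor* is one exact minimizer match between a query (read) and a
target (reference) sequence, stored as the 0-based coordinates of the
LAST base of the match on each sequence plus the match span.  All gap
arithmetic in the chaining modules is defined on these end positions.

Reverse-complement matches carry query coordinates on the
reverse-complemented read, so chaining itself is strand-agnostic and each
(rid, strand) group is chained independently.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import GroupingError, InputError

__all__ = [
    "Anchor",
    "AnchorSet",
    "ChainState",
    "MapParams",
    "sort_anchors",
    "read_anchor_tsv",
    "write_anchor_tsv",
]


@dataclasses.dataclass(frozen=True)
class Anchor:
    """One exact match: end coordinates (x on reference, y on query) and span w."""

    x: int
    y: int
    w: int
    rid: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"anchor span must be positive, got w={self.w}")
        if self.x < self.w - 1 or self.y < self.w - 1:
            raise ValueError(
                f"match does not fit in sequence: x={self.x} y={self.y} w={self.w}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclasses.dataclass
class AnchorSet:
    """Sorted anchors of one read against one (rid, strand) target group.

    Stored columnar (int64 arrays) because the chaining kernels operate on
    arrays; `__getitem__` materialises individual :class:`Anchor` objects.
    Ordering invariant: lexicographic by (x, y), stable on full ties.
    """

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray
    rid: int = 0
    strand: str = "+"
    read_id: str = ""
    read_length: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=np.int64)
        if not (self.x.shape == self.y.shape == self.w.shape):
            raise ValueError("x, y, w arrays must have identical shape")

    def __len__(self) -> int:
        return int(self.x.size)

    def __getitem__(self, i: int) -> Anchor:
        return Anchor(
            int(self.x[i]), int(self.y[i]), int(self.w[i]), self.rid, self.strand
        )

    def __iter__(self) -> Iterator[Anchor]:
        for i in range(len(self)):
            yield self[i]

    @property
    def anchors(self) -> list[Anchor]:
        return list(self)

    @property
    def avg_span(self) -> float:
        """Mean anchor span, computed once over the whole set (0.0 when empty)."""
        return float(self.w.mean()) if len(self) else 0.0

    def is_sorted(self) -> bool:
        if len(self) < 2:
            return True
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        return bool(np.all((dx > 0) | ((dx == 0) & (dy >= 0))))


@dataclasses.dataclass
class ChainState:
    """Per-anchor chaining DP output.

    S[i]  best chaining score ending at anchor i (>= w_i);
    P[i]  optimal predecessor index, -1 for a chain start;
    V[i]  maximum of S along the chain from its start up to i:
          V[i] = max(S[i], V[P[i]]) when P[i] >= 0 else S[i].
    """

    S: np.ndarray
    P: np.ndarray
    V: np.ndarray

    def __len__(self) -> int:
        return int(self.S.size)

    def __eq__(self, other: object) -> bool:  # integer, field-by-field
        if not isinstance(other, ChainState):
            return NotImplemented
        return (
            np.array_equal(self.S, other.S)
            and np.array_equal(self.P, other.P)
            and np.array_equal(self.V, other.V)
        )


DEFAULT_PROBE_DELTAS = (0, 16, 512, 1024, 2048, 3072, 4096, 5000)


@dataclasses.dataclass(frozen=True)
class MapParams:
    """All mapping thresholds.

    k / wmin           minimizer seeding preset (ONT-style defaults);
    max_dist_x / _y    maximum reference / query gap between chained anchors;
    bandwidth          maximum |query_gap - reference_gap|;
    max_range          cap on the number of predecessors/successors examined;
    probe_deltas       probe offsets of the successor-range speed heuristic,
                       strictly increasing, starting at 0, ending at max_range;
    max_skip           predecessor-scan early-exit heuristic (None = unbounded,
                       which is the exact, parallelisable configuration);
    min_score/min_cnt  chain emission thresholds;
    mask_level         query-overlap fraction above which a chain is secondary;
    max_occ            optional minimizer occurrence cutoff (None = off).
    """

    k: int = 15
    wmin: int = 10
    max_dist_x: int = 5000
    max_dist_y: int = 5000
    bandwidth: int = 500
    max_range: int = 5000
    probe_deltas: tuple[int, ...] = DEFAULT_PROBE_DELTAS
    max_skip: int | None = None
    min_score: int = 40
    min_cnt: int = 3
    mask_level: float = 0.5
    max_occ: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.wmin < 1:
            raise ValueError("k and wmin must be >= 1")
        if self.k > 31:
            raise ValueError("k must fit in a 64-bit packed k-mer (k <= 31)")
        d = self.probe_deltas
        if len(d) == 0 or d[0] != 0 or d[-1] != self.max_range:
            raise ValueError(
                "probe_deltas must start at 0 and end at max_range "
                f"(got {d}, max_range={self.max_range})"
            )
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("probe_deltas must be strictly increasing")
        if not (0.0 < self.mask_level <= 1.0):
            raise ValueError("mask_level must be in (0, 1]")
        if self.max_skip is not None and self.max_skip < 1:
            raise ValueError("max_skip must be >= 1 or None")

    def replace(self, **kw) -> "MapParams":
        return dataclasses.replace(self, **kw)


def sort_anchors(
    raw: Sequence[Anchor] | Iterable[Anchor],
    read_id: str = "",
    read_length: int | None = None,
) -> AnchorSet:
    """Sort anchors of one (rid, strand) group into a canonical AnchorSet.

    Sorting is lexicographic by (x, y) and stable with respect to input
    order on full ties; duplicates are preserved.  Mixing rid or strand
    raises :class:`GroupingError`.
    """
    raw = list(raw)
    if not raw:
        return AnchorSet(
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            read_id=read_id,
            read_length=read_length or 0,
        )
    rid, strand = raw[0].rid, raw[0].strand
    for a in raw:
        if a.rid != rid or a.strand != strand:
            raise GroupingError(
                f"anchors mix (rid, strand) groups: ({rid},{strand}) vs "
                f"({a.rid},{a.strand})"
            )
    x = np.fromiter((a.x for a in raw), np.int64, len(raw))
    y = np.fromiter((a.y for a in raw), np.int64, len(raw))
    w = np.fromiter((a.w for a in raw), np.int64, len(raw))
    order = np.lexsort((y, x))  # stable: ties keep input order
    if read_length is None:
        read_length = int(y.max()) + 1
    return AnchorSet(
        x[order], y[order], w[order], rid, strand, read_id, read_length
    )


# ---------------------------------------------------------------------------
# Anchor TSV dialect: one row per anchor, columns
#   read_id  rid  strand  x  y  w
# header lines start with '#'.

_TSV_HEADER = "#read_id\trid\tstrand\tx\ty\tw"


def write_anchor_tsv(sets: Iterable[AnchorSet], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for s in sets:
            for a in s:
                fh.write(
                    f"{s.read_id}\t{a.rid}\t{a.strand}\t{a.x}\t{a.y}\t{a.w}\n"
                )


def read_anchor_tsv(path) -> list[AnchorSet]:
    """Read the anchor TSV dialect, grouping rows by (read_id, rid, strand).

    Groups are returned in order of first appearance; each group is sorted
    via :func:`sort_anchors`.  Malformed rows raise :class:`InputError`
    with the offending line number.
    """
    groups: dict[tuple[str, int, str], list[Anchor]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise InputError(
                    f"{path}:{ln}: expected 6 tab-separated columns, got {len(parts)}"
                )
            read_id, rid_s, strand, xs, ys, ws = parts
            try:
                anchor = Anchor(int(xs), int(ys), int(ws), int(rid_s), strand)
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: {exc}") from exc
            groups.setdefault((read_id, anchor.rid, strand), []).append(anchor)
    return [
        sort_anchors(anchors, read_id=key[0]) for key, anchors in groups.items()
    ]


def check_v_recurrence(state: ChainState) -> bool:
    """True iff V satisfies V[i] = max(S[i], V[P[i]]) (V[i]=S[i] at starts)."""
    S, P, V = state.S, state.P, state.V
    for i in range(len(state)):
        expect = S[i] if P[i] < 0 else max(S[i], V[P[i]])
        if V[i] != expect:
            return False
    return True


def backtrack_path_max(state: ChainState, i: int) -> int:
    """Max of S along i, P[i], P[P[i]], ... — the quantity V[i] caches."""
    best = -math.inf
    while i >= 0:
        best = max(best, int(state.S[i]))
        i = int(state.P[i])
    return int(best)
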