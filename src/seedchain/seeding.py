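"""Minimizer seeding: reference hash index and per-read anchor collection.

The reference is indexed into a multimap from 64-bit minimizer hashes to
(rid, end position, strand) postings.  A read's minimizers query the
index; every hash match with a consistent strand product becomes one
anchor of span k.  Reverse-strand anchors carry query coordinates on the
reverse-complemented read so that each (rid, strand) group is a plain
collinear chaining problem.

Conventions (fixed, unseeded — identical inputs give identical output):
canonical k-mer = lexicographic minimum of the 2-bit packed k-mer and its
reverse complement (k-mers equal to their own reverse complement are
skipped); hash = a fixed invertible 64-bit mix; winnowing picks the
leftmost minimal hash per window of ``wmin`` consecutive k-mers and
reports each selected position once; k-mers covering non-ACGT characters
are skipped.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .errors import IndexBuildError
from .model import AnchorSet, MapParams

__all__ = [
    "extract_minimizers",
    "MinimizerIndex",
    "build_index",
    "collect_anchors",
]

_CODE = np.full(256, 4, np.int8)
for _i, _ch in enumerate("ACGT"):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]


def _minimizer_arrays(seq: str, k: int, wmin: int):
    if k < 1 or wmin < 1:
        raise ValueError("k and wmin must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    if len(seq) < k:
        return (
            np.empty(0, np.uint64),
            np.empty(0, np.int64),
            np.empty(0, np.int8),
        )
    kmask = np.uint64((1 << (2 * k)) - 1)
    return _kernels.minimizer_scan_kernel(_encode(seq), k, wmin, kmask)


def extract_minimizers(seq: str, k: int, wmin: int) -> list[tuple[int, int, str]]:
    """(wmin, k)-minimizers of ``seq`` as (hash, 0-based end position, strand)."""
    h, pos, s = _minimizer_arrays(seq, k, wmin)
    return [
        (int(h[i]), int(pos[i]), "+-"[int(s[i])]) for i in range(pos.size)
    ]


@dataclasses.dataclass
class MinimizerIndex:
    """Multimap from minimizer hash to reference postings, stored CSR-style.

    ``hashes`` is sorted; ``rid``/``pos``/``strand`` are parallel posting
    arrays (ties ordered by (rid, pos) for determinism).  Querying a hash
    absent from the table yields an empty slice.
    """

    k: int
    wmin: int
    hashes: np.ndarray
    rid: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    names: list[str]
    lengths: list[int]

    @property
    def n_postings(self) -> int:
        return int(self.hashes.size)

    @property
    def n_keys(self) -> int:
        if self.hashes.size == 0:
            return 0
        return int(np.unique(self.hashes).size)

    def query(self, h: int):
        """Postings for one hash: (rid, pos, strand) arrays (possibly empty)."""
        lo = int(np.searchsorted(self.hashes, np.uint64(h), "left"))
        hi = int(np.searchsorted(self.hashes, np.uint64(h), "right"))
        return self.rid[lo:hi], self.pos[lo:hi], self.strand[lo:hi]


def build_index(
    reference: Iterable[tuple[str, str]] | Sequence[tuple[str, str]],
    params: MapParams,
) -> MinimizerIndex:
    """Index every record's minimizers; multi-occurring keys keep all postings."""
    names: list[str] = []
    lengths: list[int] = []
    hs, rids, poss, strands = [], [], [], []
    for name, seq in reference:
        if len(seq) == 0:
            continue
        r = len(names)
        names.append(name)
        lengths.append(len(seq))
        h, p, s = _minimizer_arrays(seq, params.k, params.wmin)
        hs.append(h)
        rids.append(np.full(p.size, r, np.int64))
        poss.append(p)
        strands.append(s)
    if not names:
        raise IndexBuildError("reference contains no non-empty records")
    h = np.concatenate(hs) if hs else np.empty(0, np.uint64)
    rid = np.concatenate(rids) if rids else np.empty(0, np.int64)
    pos = np.concatenate(poss) if poss else np.empty(0, np.int64)
    strand = np.concatenate(strands) if strands else np.empty(0, np.int8)
    order = np.lexsort((pos, rid, h))
    return MinimizerIndex(
        params.k, params.wmin, h[order], rid[order], pos[order], strand[order],
        names, lengths,
    )


def collect_anchors(
    index: MinimizerIndex,
    read: tuple[str, str],
    params: MapParams,
) -> list[AnchorSet]:
    """Anchors of one read against the index, grouped by (rid, strand).

    Each group is sorted by (x, y), stable in match-generation order.  A
    read shorter than k (or sharing no minimizers) yields an empty list.
    ``params.max_occ`` drops read minimizers whose hash occurs more often
    in the index (default off).
    """
    if index.k != params.k or index.wmin != params.wmin:
        raise ValueError("index and params disagree on (k, wmin)")
    read_id, seq = read
    L = len(seq)
    h, y0, sr = _minimizer_arrays(seq, params.k, params.wmin)
    if h.size == 0:
        return []
    lo = np.searchsorted(index.hashes, h, "left")
    hi = np.searchsorted(index.hashes, h, "right")
    counts = hi - lo
    if params.max_occ is not None:
        counts = np.where(counts > params.max_occ, 0, counts)
    total = int(counts.sum())
    if total == 0:
        return []
    # flatten posting slices: posting index array of length `total`
    offs = np.cumsum(counts)
    ids = np.arange(total, dtype=np.int64) - np.repeat(offs - counts, counts) \
        + np.repeat(lo, counts)
    rid_a = index.rid[ids]
    x_a = index.pos[ids]
    st_a = index.strand[ids]
    y0_a = np.repeat(y0, counts)
    sr_a = np.repeat(sr, counts)
    strand_a = (st_a ^ sr_a).astype(np.int8)
    k = params.k
    y_a = np.where(strand_a == 0, y0_a, L + k - 2 - y0_a).astype(np.int64)
    key = rid_a * 2 + strand_a
    order = np.lexsort((y_a, x_a, key))  # stable within (x, y) ties
    key_s = key[order]
    out: list[AnchorSet] = []
    boundaries = np.flatnonzero(np.diff(key_s)) + 1
    for chunk in np.split(order, boundaries):
        g_rid = int(rid_a[chunk[0]])
        g_strand = "+-"[int(strand_a[chunk[0]])]
        out.append(
            AnchorSet(
                x_a[chunk],
                y_a[chunk],
                np.full(chunk.size, k, np.int64),
                g_rid,
                g_strand,
                read_id,
                L,
            )
        )
    return out
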