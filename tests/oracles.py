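"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the stated definitions in
plain Python (no shared code with the package kernels): an O(n^2)
exhaustive chaining DP, a linear-scan successor range, and a brute-force
window-scan minimizer extractor.
"""

from __future__ import annotations

import numpy as np

from seedchain.model import AnchorSet, MapParams
from seedchain.simulate import (
    AnchorSimSpec,
    plant_chains,
    random_anchor_set,
    tie_rich_anchor_set,
)

MASK64 = (1 << 64) - 1


def brute_pair_score(xi, yi, xj, yj, wj, avg_span, p: MapParams):
    """Pair score from the stated closed form; None when unchainable."""
    dr = xj - xi
    dq = yj - yi
    if dr <= 0 or dq <= 0 or dq > p.max_dist_y or dr > p.max_dist_x:
        return None
    dd = abs(dq - dr)
    if dd > p.bandwidth:
        return None
    match = min(dq, dr, wj)
    log_half = (dd.bit_length() - 1) // 2 if dd > 0 else 0
    return match - (int(0.01 * avg_span * dd) + log_half)


def brute_chain(aset: AnchorSet, p: MapParams):
    """Exhaustive O(n^2) DP: every (i, j) pair within the predecessor cap,
    strict improvement scanning i downward (nearest predecessor wins ties)."""
    n = len(aset)
    x, y, w = aset.x, aset.y, aset.w
    avg = float(w.mean()) if n else 0.0
    S = [0] * n
    P = [-1] * n
    V = [0] * n
    for j in range(n):
        best, bp = int(w[j]), -1
        for i in range(j - 1, max(0, j - p.max_range) - 1, -1):
            sc = brute_pair_score(int(x[i]), int(y[i]), int(x[j]), int(y[j]),
                                  int(w[j]), avg, p)
            if sc is None:
                continue
            cand = S[i] + sc
            if cand > best:
                best, bp = cand, i
        S[j], P[j] = best, bp
        V[j] = V[bp] if bp >= 0 and V[bp] > best else best
    return np.array(S, np.int64), np.array(P, np.int64), np.array(V, np.int64)


def linear_successor_end(aset: AnchorSet, i: int, p: MapParams) -> int:
    """Largest exclusive end with every successor within the reference-gap
    threshold, capped at i+1+max_range and n — by definition, one step at
    a time."""
    n = len(aset)
    e = i
    for j in range(i + 1, min(n, i + 1 + p.max_range)):
        if aset.x[j] - aset.x[i] > p.max_dist_x:
            break
        e = j
    return e + 1


# ---------------------------------------------------------------------------
# Minimizer oracle


def py_hash64(key: int, mask: int) -> int:
    key = (~key + (key << 21)) & mask
    key = key ^ (key >> 24)
    key = (key + (key << 3) + (key << 8)) & mask
    key = key ^ (key >> 14)
    key = (key + (key << 2) + (key << 4)) & mask
    key = key ^ (key >> 28)
    key = (key + (key << 31)) & mask
    return key


_C = {"A": 0, "C": 1, "G": 2, "T": 3}


def py_minimizers(seq: str, k: int, wmin: int):
    """Brute-force window scan with leftmost-minimum tie-break."""
    seq = seq.upper()
    n = len(seq)
    mask = (1 << (2 * k)) - 1
    info: dict[int, tuple[int, str]] = {}
    for start in range(n - k + 1):
        kmer = seq[start : start + k]
        if any(c not in _C for c in kmer):
            continue
        fwd = 0
        rev = 0
        for c in kmer:
            fwd = fwd * 4 + _C[c]
        for c in reversed(kmer):
            rev = rev * 4 + (3 - _C[c])
        if fwd == rev:
            continue
        canon, strand = (fwd, "+") if fwd < rev else (rev, "-")
        info[start + k - 1] = (py_hash64(canon, mask), strand)
    out = []
    last = None
    for e in range(k - 1 + wmin - 1, n):
        window = [pp for pp in range(e - wmin + 1, e + 1) if pp in info]
        if not window:
            continue
        best = min(window, key=lambda pp: (info[pp][0], pp))
        if best != last:
            out.append((info[best][0], best, info[best][1]))
            last = best
    return out


# ---------------------------------------------------------------------------
# Randomised set battery shared by differential tests


def anchor_battery(n_sets: int, seed0: int, max_n: int = 2000):
    """Yield a mix of dense, sparse, tie-rich and planted anchor sets."""
    rng = np.random.default_rng(seed0)
    for s in range(n_sets):
        kind = s % 4
        seed = int(rng.integers(0, 2**31 - 1))
        n = int(rng.integers(1, max_n + 1))
        if kind == 0:
            yield random_anchor_set(n, seed, span_factor=0.5, w_range=(10, 20))
        elif kind == 1:
            yield random_anchor_set(n, seed, span_factor=20.0)
        elif kind == 2:
            yield tie_rich_anchor_set(n, seed)
        else:
            chain_len = max(1, min(40, n // 4))
            n_chains = max(1, min(4, n // (chain_len * 2) or 1))
            spec = AnchorSimSpec(
                n_chains=n_chains,
                chain_len=chain_len,
                noise_anchors=max(0, n - n_chains * chain_len),
                read_length=max(30_000, n * 30),
                gap_mean=100,
                gap_jitter=30,
                seed=seed,
            )
            yield plant_chains(spec)[0]
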