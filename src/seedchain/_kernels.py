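"""Numba-compiled hot loops shared by seeding and chaining.

Everything here operates on plain int64/uint64 arrays; the public modules
wrap these kernels with the dataclass API.  Integer semantics are chosen
to be exactly reproducible: the gap penalty truncates the float product
toward zero (a C-style cast) and the half-log term uses floor(log2),
the arithmetic a leading-zero count gives on 32-bit integers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Out-of-band "pair cannot be chained" signal for the scalar kernel.
NO_CHAIN_SENTINEL = np.int64(np.iinfo(np.int64).min)

_U2 = np.uint64(2)
_U3 = np.uint64(3)


@njit(cache=True)
def ilog2(v):
    """floor(log2 v) for v >= 1, and 0 for v == 0 (clz-style integer log)."""
    r = np.int64(0)
    while v > 1:
        v >>= 1
        r += 1
    return r


@njit(cache=True)
def pair_score_kernel(xi, yi, xj, yj, wj, avg_span, max_dist_x, max_dist_y, bandwidth):
    """Chain score contribution of predecessor i -> successor j.

    Returns NO_CHAIN_SENTINEL when any pair filter fails, otherwise
    match - penalty where match = min(dq, dr, wj) and
    penalty = trunc(0.01 * avg_span * dd) + (ilog2(dd) >> 1).
    """
    dr = xj - xi
    dq = yj - yi
    if dr <= 0 or dq <= 0 or dq > max_dist_y or dr > max_dist_x:
        return NO_CHAIN_SENTINEL
    dd = dr - dq
    if dd < 0:
        dd = -dd
    if dd > bandwidth:
        return NO_CHAIN_SENTINEL
    mm = dq if dq < dr else dr
    if wj < mm:
        mm = wj
    pen = np.int64(int(0.01 * avg_span * dd)) + (ilog2(dd) >> 1)
    return mm - pen


@njit(cache=True)
def chain_backward_kernel(x, y, w, avg_span, max_dist_x, max_dist_y, bandwidth,
                          max_range, max_skip):
    """Predecessor-order chaining DP (classic sequential formulation).

    For each anchor j (ascending) the scan runs i = j-1 down to the start
    of the predecessor range; strict improvement only, so the NEAREST
    predecessor wins score ties.  max_skip < 0 means unbounded (exact);
    otherwise the scan stops after max_skip consecutive non-improving
    valid candidates (the speed heuristic).
    """
    n = x.size
    S = np.empty(n, np.int64)
    P = np.full(n, np.int64(-1))
    V = np.empty(n, np.int64)
    st = 0
    for j in range(n):
        while st < j and x[j] - x[st] > max_dist_x:
            st += 1
        lo = st
        if j - lo > max_range:
            lo = j - max_range
        best = w[j]
        bp = np.int64(-1)
        nskip = 0
        for i in range(j - 1, lo - 1, -1):
            sc = pair_score_kernel(x[i], y[i], x[j], y[j], w[j], avg_span,
                                   max_dist_x, max_dist_y, bandwidth)
            if sc == NO_CHAIN_SENTINEL:
                continue
            cand = S[i] + sc
            if cand > best:
                best = cand
                bp = i
                nskip = 0
            else:
                nskip += 1
                if max_skip >= 0 and nskip >= max_skip:
                    break
        S[j] = best
        P[j] = bp
        if bp >= 0 and V[bp] > best:
            V[j] = V[bp]
        else:
            V[j] = best
    return S, P, V


@njit(cache=True)
def successor_ranges_kernel(x, max_dist_x, max_range, deltas):
    """Exclusive successor-range end per anchor via the probe heuristic.

    Probes deltas in ascending order (first element 0), stops at the first
    out-of-threshold probe (positions beyond the array count as
    out-of-threshold), then decrements to the exact boundary.  Because x
    is sorted this equals the linear-scan answer.
    """
    n = x.size
    end_idx = np.empty(n, np.int64)
    for i in range(n):
        e = i + max_range
        for t in range(deltas.size):
            p = i + deltas[t]
            if p >= n or x[p] - x[i] > max_dist_x:
                e = p
                break
        if e > n - 1:
            e = n - 1
        while x[e] - x[i] > max_dist_x:
            e -= 1
        end_idx[i] = e + 1
    return end_idx


@njit(cache=True)
def chain_forward_kernel(x, y, w, end_idx, is_source, avg_span,
                         max_dist_x, max_dist_y, bandwidth):
    """Forward-transformed chaining DP: each anchor pushes to its successors.

    Sources are processed in ascending order, so S[i]/P[i] are final when
    anchor i pushes; V[i] is finalised at that point.  Update rule: accept
    s >= S[j] except the tie s == S[j] == w_j (never give a not-yet-chained
    anchor a predecessor on a tie with its own span).  Applied uniformly to
    every successor, this makes the nearest source win ties, reproducing
    the backward scan bit-for-bit.  is_source masks anchors whose successor
    range is empty (the condensed-workload optimisation); masking them off
    must not change the result.
    """
    n = x.size
    S = np.empty(n, np.int64)
    P = np.full(n, np.int64(-1))
    V = np.empty(n, np.int64)
    for j in range(n):
        S[j] = w[j]
    for i in range(n):
        si = S[i]
        pi = P[i]
        if pi >= 0 and V[pi] > si:
            V[i] = V[pi]
        else:
            V[i] = si
        if not is_source[i]:
            continue
        for j in range(i + 1, end_idx[i]):
            sc = pair_score_kernel(x[i], y[i], x[j], y[j], w[j], avg_span,
                                   max_dist_x, max_dist_y, bandwidth)
            if sc == NO_CHAIN_SENTINEL:
                continue
            s = si + sc
            if s > S[j] or (s == S[j] and S[j] != w[j]):
                S[j] = s
                P[j] = i
    return S, P, V


# ---------------------------------------------------------------------------
# Minimizer seeding


@njit(cache=True)
def hash64(key, mask):
    """Fixed invertible 64-bit integer mix over a 2k-bit packed k-mer."""
    key = (~key + (key << np.uint64(21))) & mask
    key = key ^ (key >> np.uint64(24))
    key = (key + (key << np.uint64(3)) + (key << np.uint64(8))) & mask
    key = key ^ (key >> np.uint64(14))
    key = (key + (key << np.uint64(2)) + (key << np.uint64(4))) & mask
    key = key ^ (key >> np.uint64(28))
    key = (key + (key << np.uint64(31))) & mask
    return key


@njit(cache=True)
def minimizer_scan_kernel(codes, k, wmin, kmask):
    """(wmin, k)-minimizer winnowing over 2-bit base codes.

    codes: int8 array, 0..3 = ACGT, anything else = ambiguous.  K-mers
    covering ambiguous bases, and k-mers equal to their own reverse
    complement, are skipped.  Every full window of wmin consecutive k-mer
    positions selects the leftmost minimal-hash valid k-mer; consecutive
    windows selecting the same position emit it once.  Returns
    (hash uint64[], end position int64[], strand int8[] with 0='+').
    """
    n = codes.size
    hval = np.empty(n, np.uint64)
    strand = np.zeros(n, np.int8)
    ok = np.zeros(n, np.uint8)
    shift = np.uint64(2 * (k - 1))
    fwd = np.uint64(0)
    rev = np.uint64(0)
    run = 0
    for p in range(n):
        c = codes[p]
        if c < 0 or c > 3:
            run = 0
            fwd = np.uint64(0)
            rev = np.uint64(0)
            continue
        run += 1
        fwd = ((fwd << _U2) | np.uint64(c)) & kmask
        rev = (rev >> _U2) | ((_U3 - np.uint64(c)) << shift)
        if run >= k and fwd != rev:
            km = fwd if fwd < rev else rev
            hval[p] = hash64(km, kmask)
            ok[p] = 1
            strand[p] = 0 if fwd < rev else 1
    out_h = np.empty(n, np.uint64)
    out_pos = np.empty(n, np.int64)
    out_s = np.empty(n, np.int8)
    m = 0
    last = -1
    first_end = k - 1 + wmin - 1  # last k-mer position of the first full window
    for e in range(first_end, n):
        best = -1
        for p in range(e - wmin + 1, e + 1):
            if ok[p] and (best < 0 or hval[p] < hval[best]):
                best = p
        if best >= 0 and best != last:
            out_h[m] = hval[best]
            out_pos[m] = best
            out_s[m] = strand[best]
            m += 1
            last = best
    return out_h[:m], out_pos[:m], out_s[:m]
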