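"""Banded affine-gap global alignment kernel (Gotoh three-state DP).

Sequences are encoded as uint8 IUPAC bitmasks; two bases "match" when their
bitmasks intersect. The band is defined per row by inclusive column bounds
``lo[i]..hi[i]`` around a guide path; cells outside the band are -inf. A gap
of length k costs ``gap_open + k * gap_extend``.

The traceback reports whether the optimal path touched a band edge that is
not a matrix boundary — the caller widens the band and retries in that case,
so the returned score equals the unbanded optimum once no edge is touched.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

# traceback byte layout: bits 0-1 = predecessor state of M,
# bits 2-3 = of X (gap in B, consumes A), bits 4-5 = of Y (gap in A).
# states: 0 = M, 1 = X, 2 = Y


@njit(cache=True)
def _fill(a, b, lo, hi, match, mismatch, gap_open, gap_extend, tb):
    m = a.shape[0]
    W = tb.shape[1]
    Mp = np.full(W, NEG)
    Xp = np.full(W, NEG)
    Yp = np.full(W, NEG)
    Mc = np.full(W, NEG)
    Xc = np.full(W, NEG)
    Yc = np.full(W, NEG)
    # row 0: only leading gaps in A (state Y) or the empty prefix
    for j in range(lo[0], hi[0] + 1):
        off = j - lo[0]
        if j == 0:
            Mp[off] = 0.0
        else:
            Yp[off] = gap_open + gap_extend * j
            tb[0, off] = 2 << 4
    for i in range(1, m + 1):
        loi = lo[i]
        hii = hi[i]
        lop = lo[i - 1]
        hip = hi[i - 1]
        for off in range(W):
            Mc[off] = NEG
            Xc[off] = NEG
            Yc[off] = NEG
        ai = a[i - 1]
        for j in range(loi, hii + 1):
            off = j - loi
            code = np.uint8(0)
            if j == 0:
                Xc[off] = gap_open + gap_extend * i
                code |= np.uint8(1 << 2)
                tb[i, off] = code
                continue
            # M from (i-1, j-1)
            if lop <= j - 1 <= hip:
                po = j - 1 - lop
                best = Mp[po]
                st = 0
                if Xp[po] > best:
                    best = Xp[po]
                    st = 1
                if Yp[po] > best:
                    best = Yp[po]
                    st = 2
                if best > NEG / 2:
                    s = match if (ai & b[j - 1]) != 0 else mismatch
                    Mc[off] = best + s
                    code |= np.uint8(st)
            # X from (i-1, j)
            if lop <= j <= hip:
                po = j - lop
                best = Mp[po] + gap_open + gap_extend
                st = 0
                v = Xp[po] + gap_extend
                if v > best:
                    best = v
                    st = 1
                v = Yp[po] + gap_open + gap_extend
                if v > best:
                    best = v
                    st = 2
                if best > NEG / 2:
                    Xc[off] = best
                    code |= np.uint8(st << 2)
            # Y from (i, j-1)
            if j - 1 >= loi:
                po = off - 1
                best = Mc[po] + gap_open + gap_extend
                st = 0
                v = Xc[po] + gap_open + gap_extend
                if v > best:
                    best = v
                    st = 1
                v = Yc[po] + gap_extend
                if v > best:
                    best = v
                    st = 2
                if best > NEG / 2:
                    Yc[off] = best
                    code |= np.uint8(st << 4)
            tb[i, off] = code
        for off in range(W):
            Mp[off] = Mc[off]
            Xp[off] = Xc[off]
            Yp[off] = Yc[off]
    return Mp, Xp, Yp


@njit(cache=True)
def _traceback(tb, lo, hi, n, start_state, m):
    ops = np.empty(m + n, np.uint8)
    k = 0
    i = m
    j = n
    st = start_state
    edge = False
    while i > 0 or j > 0:
        if (j == lo[i] and lo[i] > 0) or (j == hi[i] and hi[i] < n):
            edge = True
        byte = tb[i, j - lo[i]]
        if st == 0:
            ops[k] = 0
            st = byte & 3
            i -= 1
            j -= 1
        elif st == 1:
            ops[k] = 1
            st = (byte >> 2) & 3
            i -= 1
        else:
            ops[k] = 2
            st = (byte >> 4) & 3
            j -= 1
        k += 1
    return ops[:k], edge


def banded_align(a: np.ndarray, b: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                 match: float, mismatch: float, gap_open: float,
                 gap_extend: float):
    """Run the banded DP; return (score, ops, edge_touched).

    ``ops`` is a uint8 array over the optimal path in order: 0 = aligned
    column (consumes one base of each), 1 = gap in b (consumes a), 2 = gap
    in a (consumes b).
    """
    m, n = a.shape[0], b.shape[0]
    W = int(np.max(hi - lo)) + 1
    tb = np.zeros((m + 1, W), np.uint8)
    Mf, Xf, Yf = _fill(a, b, lo, hi, float(match), float(mismatch),
                       float(gap_open), float(gap_extend), tb)
    off = n - lo[m]
    finals = (Mf[off], Xf[off], Yf[off])
    st = int(np.argmax(np.array(finals)))
    score = finals[st]
    if score < NEG / 2:
        raise RuntimeError("band disconnected: no path to the final cell")
    ops, edge = _traceback(tb, lo, hi, n, st, m)
    return float(score), ops[::-1].copy(), bool(edge)
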