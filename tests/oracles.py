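"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the package
implementation: a full-matrix affine-gap DP (score only), doubled-sequence
motif scans, exhaustive overlap checks, nearest-flanking-marker search,
circular run counting and bitmap set algebra.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def full_gotoh_score(sa: str, sb: str, match: float, mismatch: float,
                     gap_open: float, gap_extend: float) -> float:
    """Full quadratic-space global affine-gap alignment score.

    Gap of length k costs gap_open + k * gap_extend. Row-wise recurrence:
    vertical-gap state from the previous row, horizontal-gap state by a
    prefix-max scan within the row.
    """
    m, n = len(sa), len(sb)
    eb = np.frombuffer(sb.encode(), np.uint8)
    M = np.full(n + 1, NEG)
    X = np.full(n + 1, NEG)
    Y = np.full(n + 1, NEG)
    M[0] = 0.0
    js = np.arange(1, n + 1)
    Y[1:] = gap_open + gap_extend * js
    for i in range(1, m + 1):
        sub = np.where(eb == ord(sa[i - 1]), match, mismatch)
        best_prev = np.maximum(np.maximum(M, X), Y)
        nM = np.full(n + 1, NEG)
        nM[1:] = best_prev[:-1] + sub
        nX = np.maximum(M + gap_open + gap_extend,
                        np.maximum(X + gap_extend, Y + gap_open + gap_extend))
        # horizontal gaps: Y[j] = max_{k<j} (max(nM,nX)[k] + open + ext*(j-k))
        nY = np.full(n + 1, NEG)
        A = np.maximum(nM, nX)[:-1] + gap_open - gap_extend * np.arange(n)
        nY[1:] = np.maximum.accumulate(A) + gap_extend * js
        M, X, Y = nM, nX, nY
    return float(max(M[n], X[n], Y[n]))


def naive_find_sites(seq: str, motif: str, circular: bool) -> list[int]:
    """Scan seq+seq (doubled) restricted to starts < length."""
    space = seq + seq if circular else seq
    hits = []
    for i in range(len(seq)):
        if i + len(motif) <= len(space) and space[i:i + len(motif)] == motif:
            hits.append(i + 1)
    return hits


def circ_points(start: int, end: int, n: int) -> set[int]:
    """0-based base indices of the 1-based inclusive circular interval."""
    length = (end - start) % n + 1
    return {(start - 1 + k) % n for k in range(length)}


def naive_overlap(frag: tuple[int, int, int], probe: tuple[int, int],
                  n: int) -> bool:
    return bool(circ_points(frag[0], frag[1], n) & circ_points(*probe, n))


def nearest_flanking_intervals(marker_pos: list[int],
                               crossovers: list[int],
                               n: int) -> set[tuple[int, int]]:
    """For each true crossover (exchange between base c and c+1), the open
    interval between the nearest marker at or below c and the nearest marker
    strictly above c, around the circle."""
    ms = sorted(marker_pos)
    out = set()
    for c in crossovers:
        below = [p for p in ms if p <= c]
        above = [p for p in ms if p > c]
        left = below[-1] if below else ms[-1]
        right = above[0] if above else ms[0]
        out.add((left, right))
    return out


def min_circular_switches(states: list[str]) -> int:
    """Minimum number of origin switches consistent with a circular state
    sequence = number of maximal runs (0 if uniform)."""
    runs = 1
    for a, b in zip(states, states[1:]):
        if a != b:
            runs += 1
    if len(states) > 1 and states[0] == states[-1] and runs > 1:
        runs -= 1
    return 0 if runs == 1 else runs


def bitmap_intersection(positive_masks: list[np.ndarray],
                        negative_masks: list[np.ndarray]) -> np.ndarray:
    out = np.ones_like(positive_masks[0])
    for m in positive_masks:
        out &= m
    for m in negative_masks:
        out &= ~m
    return out


def circ_dist(x: int, y: int, n: int) -> int:
    d = (x - y) % n
    return min(d, n - d)
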