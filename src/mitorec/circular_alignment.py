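"""Full-length pairwise alignment of diverged circular genomes.

Two circular mitochondrial genomes (roughly 93-99% identity, with indels
and a length-polymorphic low-complexity AT-rich control region) are aligned
in three stages:

1. rotation anchoring — both circles are rotated so that a longest shared
   unique exact match starts at position 1, removing the arbitrary origin;
2. anchor chaining — unique shared k-mers are merged into maximal exact
   matches and chained by a weighted longest-increasing-subsequence pass,
   giving a monotone guide path through the DP matrix;
3. banded affine-gap DP around the guide path, with the band auto-doubling
   whenever the optimal path touches a band edge, so the final score equals
   the unbanded optimum.

All reported coordinates are 1-based positions in the *original* (unrotated)
genomes; the applied rotations are recorded on the alignment object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._banded import banded_align
from .genome_io import IUPAC, CircularGenome

log = logging.getLogger(__name__)

GAP = 0  # sentinel in position arrays

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_ENCODE = np.zeros(256, np.uint8)
for _code, _bases in IUPAC.items():
    _ENCODE[ord(_code)] = sum(_BITS[b] for b in _bases)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 IUPAC bitmask array (A=1, C=2, G=4, T=8)."""
    return _ENCODE[np.frombuffer(seq.encode(), np.uint8)]


@dataclass
class AlignmentParams:
    """Scoring and heuristics for genome-scale pairwise alignment.

    Defaults are tuned for mitochondrial genome pairs at 90-99% identity
    with indels up to a few tens of bases outside the control region.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    anchor_k: int = 15
    band_width: int = 200
    mask_low_complexity: bool = True
    at_threshold: float = 0.90
    at_window: int = 200
    auto_rotate: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open <= 0 <= self.match):
            raise ValueError("require gap_open <= 0 <= match")


@dataclass
class GenomeAlignment:
    """Ordered column map between two (circular) genomes.

    ``a_pos``/``b_pos`` give, per column, the 1-based original coordinate on
    each genome or 0 (GAP). Over the rotated reading frame each genome's
    positions appear exactly once and in circular order starting at its
    rotation offset.
    """

    genome_a: str
    genome_b: str
    rotation_a: int
    rotation_b: int
    a_pos: np.ndarray
    b_pos: np.ndarray
    a_base: np.ndarray  # uint8 bitmasks, 0 at gaps
    b_base: np.ndarray
    score: float
    params: AlignmentParams
    length_a: int
    length_b: int
    masked: np.ndarray = field(default=None)  # bool per column
    _col_of_a: np.ndarray = field(default=None, repr=False)
    _col_of_b: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.masked is None:
            self.masked = np.zeros(len(self.a_pos), bool)
        self._col_of_a = np.full(self.length_a + 1, -1, np.int64)
        self._col_of_a[self.a_pos[self.a_pos > 0]] = np.nonzero(self.a_pos > 0)[0]
        self._col_of_b = np.full(self.length_b + 1, -1, np.int64)
        self._col_of_b[self.b_pos[self.b_pos > 0]] = np.nonzero(self.b_pos > 0)[0]

    def __len__(self) -> int:
        return len(self.a_pos)

    @property
    def match_cols(self) -> np.ndarray:
        """Bool per column: both sides present and bases compatible."""
        return (self.a_base & self.b_base) != 0

    def col_of_a(self, pos_a: int) -> int:
        return int(self._col_of_a[pos_a])

    def project(self, pos_a: int):
        """Map a genome-A coordinate to its genome-B partner, or None (gap)."""
        if not 1 <= pos_a <= self.length_a:
            raise ValueError(f"position {pos_a} outside 1..{self.length_a}")
        b = int(self.b_pos[self._col_of_a[pos_a]])
        return b if b != GAP else None

    def project_back(self, pos_b: int):
        if not 1 <= pos_b <= self.length_b:
            raise ValueError(f"position {pos_b} outside 1..{self.length_b}")
        a = int(self.a_pos[self._col_of_b[pos_b]])
        return a if a != GAP else None

    def column_region(self, region: tuple[int, int] | None) -> np.ndarray:
        """Bool per column: column belongs to the (circular) genome-A region.

        Gap-in-A columns inherit the nearest preceding non-gap coordinate.
        """
        if region is None:
            return np.ones(len(self), bool)
        start, end = region
        eff = self.a_pos.copy()
        # forward-fill gaps with the previous a coordinate (wrap for leading)
        last = int(eff[eff > 0][-1]) if (eff > 0).any() else 0
        for i in range(len(eff)):
            if eff[i] == GAP:
                eff[i] = last
            else:
                last = eff[i]
        n = self.length_a
        span = (end - start) % n
        return ((eff - start) % n) <= span

    def percent_identity(self, region: tuple[int, int] | None = None) -> float:
        """matches / (matches + mismatches + gapped columns) over the region."""
        sel = self.column_region(region)
        if not sel.any():
            raise ValueError("empty region")
        return float(self.match_cols[sel].sum() / sel.sum())

    def to_frame(self):
        """Column map as a DataFrame (posA, posB, baseA, baseB, masked)."""
        import pandas as pd

        inv = {v: k for k, v in _BITS.items()}
        for code, bases in IUPAC.items():
            inv.setdefault(sum(_BITS[b] for b in bases), code)
        inv[0] = "-"
        return pd.DataFrame({
            "posA": self.a_pos,
            "posB": self.b_pos,
            "baseA": [inv[int(x)] for x in self.a_base],
            "baseB": [inv[int(x)] for x in self.b_base],
            "masked": self.masked,
        })


# ---------------------------------------------------------------------------
# anchors


def _unique_kmer_index(seq: str, k: int) -> dict[str, int]:
    """0-based start of each k-mer occurring exactly once (ACGT-only k-mers)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        counts[kmer] = i if kmer not in counts else -1
    return {km: pos for km, pos in counts.items()
            if pos >= 0 and all(c in "ACGT" for c in km)}


def _shared_anchors(sa: str, sb: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal runs of shared unique k-mers as (startA, startB, length)."""
    ua = _unique_kmer_index(sa, k)
    ub = _unique_kmer_index(sb, k)
    pairs = sorted((pa, ub[km]) for km, pa in ua.items() if km in ub)
    anchors: list[tuple[int, int, int]] = []
    for pa, pb in pairs:
        if anchors and pa == anchors[-1][0] + anchors[-1][2] - k + 1 \
                and pb == anchors[-1][1] + anchors[-1][2] - k + 1:
            a0, b0, ln = anchors[-1]
            anchors[-1] = (a0, b0, ln + 1)
        else:
            anchors.append((pa, pb, k))
    return anchors


def _chain(anchors: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best colinear chain (weighted LIS by anchor length, ties by coordinate)."""
    if not anchors:
        return []
    n = len(anchors)
    best = [0.0] * n
    prev = [-1] * n
    for i, (ai, bi, li) in enumerate(anchors):
        best[i] = float(li)
        for j in range(i):
            aj, bj, lj = anchors[j]
            if aj + lj <= ai and bj + lj <= bi and best[j] + li > best[i]:
                best[i] = best[j] + li
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def rotate_to_anchor(ga: CircularGenome, gb: CircularGenome,
                     anchor_k: int = 15) -> tuple[int, int]:
    """Rotation offsets placing a longest shared unique exact match at mt1.

    Retries at half k down to 8 if no shared unique k-mer exists; raises
    ``ValueError`` with a diagnostic if none is found.
    """
    if not (ga.circular and gb.circular):
        raise ValueError("rotation anchoring requires circular genomes")
    k = anchor_k
    while k >= 8:
        anchors = _shared_anchors(ga.sequence, gb.sequence, k)
        if anchors:
            ln = max(a[2] for a in anchors)
            pa, pb, _ = min(a for a in anchors if a[2] == ln)
            return pa, pb
        k //= 2
    raise ValueError(
        f"no shared unique anchor k-mer between {ga.name} and {gb.name} "
        f"down to k=8; are these genomes related?")


# ---------------------------------------------------------------------------
# masking


def at_rich_mask(sequence: str, threshold: float = 0.90, window: int = 200,
                 circular: bool = True) -> np.ndarray:
    """Bool per base: covered by a window with A+T fraction >= threshold.

    Flags the low-complexity AT-rich control region so that markers inside
    it can be excluded from breakpoint mapping.
    """
    n = len(sequence)
    if n < window:
        window = n
    at = np.frombuffer(sequence.encode(), np.uint8)
    at = np.isin(at, np.frombuffer(b"ATW", np.uint8)).astype(np.int64)
    ext = np.concatenate([at, at[:window - 1]]) if circular else at
    csum = np.concatenate([[0], np.cumsum(ext)])
    nwin = n if circular else n - window + 1
    frac = (csum[window:window + nwin] - csum[:nwin]) / window
    mask = np.zeros(n + window, bool)
    for start in np.nonzero(frac >= threshold)[0]:
        mask[start:start + window] = True
    if circular:
        mask[:window - 1] |= mask[n:n + window - 1]
    return mask[:n]


# ---------------------------------------------------------------------------
# alignment driver


def _guide_centers(anchors, m: int, n: int) -> np.ndarray:
    """Per-row band centers: piecewise-linear through the anchor chain."""
    knots_i = [0]
    knots_j = [0]
    for pa, pb, ln in anchors:
        if pa < knots_i[-1] or pb < knots_j[-1]:
            continue
        knots_i.extend([pa, pa + ln])
        knots_j.extend([pb, pb + ln])
    if knots_i[-1] > m or knots_j[-1] > n:
        knots_i, knots_j = [0], [0]
    knots_i.append(m)
    knots_j.append(n)
    return np.interp(np.arange(m + 1), knots_i, knots_j).round().astype(np.int64)


def _align_linear(sa: str, sb: str, params: AlignmentParams):
    """Anchor-chained banded alignment of two linear strings -> (score, ops)."""
    a = encode(sa)
    b = encode(sb)
    m, n = len(a), len(b)
    anchors = _chain(_shared_anchors(sa, sb, params.anchor_k))
    centers = _guide_centers(anchors, m, n)
    width = params.band_width
    while True:
        lo = np.clip(centers - width, 0, n)
        hi = np.clip(centers + width, 0, n)
        lo[0] = 0
        hi[m] = max(hi[m], n)
        lo[m] = min(lo[m], n)
        # ensure vertical band connectivity
        np.minimum.accumulate(hi[::-1], out=hi[::-1])
        hi = np.maximum(hi, lo)
        try:
            score, ops, edge = banded_align(a, b, lo, hi, params.match,
                                            params.mismatch, params.gap_open,
                                            params.gap_extend)
        except RuntimeError:
            edge = True
        if not edge or width >= max(m, n):
            break
        width *= 2
        log.info("band overflow; widening band to %d", width)
    return score, ops


def align(ga: CircularGenome, gb: CircularGenome,
          params: AlignmentParams | None = None) -> GenomeAlignment:
    """Align two genomes end to end and return the full column map.

    Circular inputs are rotation-anchored first (unless
    ``params.auto_rotate`` is off); coordinates in the result refer to the
    original, unrotated genomes.
    """
    params = params or AlignmentParams()
    if len(ga) > 50_000 or len(gb) > 50_000:
        raise ValueError("sequences longer than 50 kb are not supported")
    rot_a = rot_b = 0
    if params.auto_rotate and ga.circular and gb.circular:
        rot_a, rot_b = rotate_to_anchor(ga, gb, params.anchor_k)
    sa = ga.rotated(rot_a).sequence if rot_a else ga.sequence
    sb = gb.rotated(rot_b).sequence if rot_b else gb.sequence
    score, ops = _align_linear(sa, sb, params)

    ncol = len(ops)
    a_pos = np.zeros(ncol, np.int64)
    b_pos = np.zeros(ncol, np.int64)
    a_base = np.zeros(ncol, np.uint8)
    b_base = np.zeros(ncol, np.uint8)
    ea, eb = encode(sa), encode(sb)
    i = j = 0
    la, lb = len(sa), len(sb)
    for c, op in enumerate(ops):
        if op != 2:  # consumes A
            a_pos[c] = (i + rot_a) % la + 1
            a_base[c] = ea[i]
            i += 1
        if op != 1:  # consumes B
            b_pos[c] = (j + rot_b) % lb + 1
            b_base[c] = eb[j]
            j += 1

    aln = GenomeAlignment(
        genome_a=ga.name, genome_b=gb.name, rotation_a=rot_a,
        rotation_b=rot_b, a_pos=a_pos, b_pos=b_pos, a_base=a_base,
        b_base=b_base, score=score, params=params, length_a=la, length_b=lb)
    if params.mask_low_complexity:
        base_mask = at_rich_mask(ga.sequence, params.at_threshold,
                                 params.at_window, ga.circular)
        col_mask = np.zeros(ncol, bool)
        col_mask[a_pos > 0] = base_mask[a_pos[a_pos > 0] - 1]
        # gap-in-A columns inherit the flag of the preceding column
        for c in range(ncol):
            if a_pos[c] == GAP and c > 0:
                col_mask[c] = col_mask[c - 1]
        aln.masked = col_mask
    return aln


def percent_identity(aln: GenomeAlignment,
                     region: tuple[int, int] | None = None) -> float:
    return aln.percent_identity(region)


def project(aln: GenomeAlignment, pos_a: int):
    return aln.project(pos_a)
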