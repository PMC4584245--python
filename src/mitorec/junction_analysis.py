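"""Junction anatomy: microhomology, resection bounds, feature proximity.

An exchange between two genomes can only be localized to the open interval
between flanking informative markers; within that interval the parents are
identical, so the interval sits inside a run of perfect parental homology —
the microhomology available to the exchange machinery. When a crossover
lies near a restriction cut site, the circular distances from the cut to
the interval bounds bracket how much end resection must have preceded the
strand exchange.

All circular distances use the shorter arc; ties break toward the
lower-coordinate direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breakpoint_mapping import CrossoverInterval
from .circular_alignment import GenomeAlignment
from .marker_calling import Marker


def _circ_dist(x: int, y: int, n: int) -> int:
    d = (x - y) % n
    return min(d, n - d)


def _in_open(p: int, left: int, right: int, n: int) -> bool:
    """Is p strictly inside the circular open interval (left, right)?"""
    span = (right - left) % n
    off = (p - left) % n
    return 0 < off < span


@dataclass
class JunctionReport:
    interval: CrossoverInterval
    microhomology: int
    resection_min: int | None = None
    resection_max: int | None = None
    markers_between_cut_and_exchange: int | None = None
    nearest_feature: str | None = None
    feature_distance: int | None = None


def microhomology(aln: GenomeAlignment, interval: CrossoverInterval,
                  markers: list[Marker] | None = None) -> int:
    """Length (bp, alignment columns) of the maximal perfect-identity run of
    the parental alignment containing the crossover interval.

    Returns 0 if a parental difference that was excluded from the marker set
    (e.g. a masked-region polymorphism) lies inside the interval itself.
    """
    match = aln.match_cols
    ncol = len(aln)
    # column span strictly between the bounding markers' difference columns
    if markers is not None:
        by_id = {m.id: m for m in markers}
        c_l = by_id[interval.left_marker].col_end
        c_r = by_id[interval.right_marker].col_start
    else:
        c_l = aln.col_of_a(interval.left)
        c_r = aln.col_of_a(interval.right)
    inner = (c_r - c_l - 1) % ncol
    run = 0
    c = (c_l + 1) % ncol
    for _ in range(inner):
        if not match[c]:
            return 0
        run += 1
        c = (c + 1) % ncol
    # extend outward through any perfect columns beyond the bounds
    c = c_l
    while match[c] and run < ncol:
        run += 1
        c = (c - 1) % ncol
    c = c_r % ncol
    while match[c] and run < ncol:
        run += 1
        c = (c + 1) % ncol
    return run


def resection_estimate(interval: CrossoverInterval, cut_position: int,
                       length: int) -> tuple[int, int]:
    """(min, max) bp trimmed from the cut for the exchange to fall in the
    interval: circular distances from the cut to the nearer and farther
    interval bounds (min 0 if the cut lies inside the interval)."""
    dl = _circ_dist(cut_position, interval.left, length)
    dr = _circ_dist(cut_position, interval.right, length)
    lo, hi = min(dl, dr), max(dl, dr)
    if _in_open(cut_position, interval.left, interval.right, length):
        lo = 0
    return lo, hi


def markers_between(markers: list[Marker], cut_position: int,
                    interval: CrossoverInterval, length: int) -> int:
    """Number of informative markers strictly between the cut and the
    interval's far bound, along the shorter arc between them."""
    dl = _circ_dist(cut_position, interval.left, length)
    dr = _circ_dist(cut_position, interval.right, length)
    far = interval.left if dl >= dr else interval.right
    fwd = (cut_position - far) % length
    if fwd <= (far - cut_position) % length:
        lo, hi = far, cut_position  # count in (far, cut) going upward
    else:
        lo, hi = cut_position, far
    return sum(1 for m in markers if _in_open(m.pos_a, lo, hi, length))


def feature_proximity(intervals: list[CrossoverInterval],
                      features: list[tuple[str, int, int]],
                      length: int) -> list[tuple[str, int]]:
    """Per crossover interval, the nearest named feature and its circular
    gap distance (0 when interval and feature overlap).

    Features are (name, start, end) in 1-based inclusive reference
    coordinates.
    """
    if not features:
        raise ValueError("empty feature list")
    out = []
    for iv in intervals:
        best = None
        for name, fs, fe in features:
            gap_up = (fs - iv.right) % length
            gap_dn = (iv.left - fe) % length
            span_iv = (iv.right - iv.left) % length
            span_f = (fe - fs) % length
            # overlap test: feature start within interval span or vice versa
            if ((fs - iv.left) % length <= span_iv
                    or (iv.left - fs) % length <= span_f):
                d = 0
            else:
                d = min(gap_up, gap_dn)
            if best is None or d < best[1]:
                best = (name, d)
        out.append(best)
    return out


def junction_report(aln: GenomeAlignment, markers: list[Marker],
                    intervals: list[CrossoverInterval],
                    cut_position: int | None = None,
                    features: list[tuple[str, int, int]] | None = None
                    ) -> list[JunctionReport]:
    """Assemble the per-crossover junction report."""
    length = aln.length_a
    prox = feature_proximity(intervals, features, length) if features else None
    reports = []
    for i, iv in enumerate(intervals):
        rep = JunctionReport(interval=iv,
                             microhomology=microhomology(aln, iv, markers))
        if cut_position is not None:
            rep.resection_min, rep.resection_max = resection_estimate(
                iv, cut_position, length)
            rep.markers_between_cut_and_exchange = markers_between(
                markers, cut_position, iv, length)
        if prox is not None:
            rep.nearest_feature, rep.feature_distance = prox[i]
        reports.append(rep)
    return reports
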