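"""Chimera segment maps and crossover-interval mapping.

Origin calls along the circular marker list are collapsed into maximal
same-origin segments; each exchange (crossover) is reported as the open
interval between the last marker of the upstream segment and the first
marker of the downstream one — the nearest flanking informative markers,
which is the finest resolution the data permit. A circular chimera always
has an even number of crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import CircularGenome
from .marker_calling import (DE_NOVO, HETEROPLASMIC, MISSING, P1, P2,
                             Marker, OriginCall)


@dataclass
class Segment:
    origin: str  # P1 | P2
    first_marker: int  # marker id
    last_marker: int
    start: int  # genome-A coordinate of first marker
    end: int  # genome-A coordinate of last marker
    n_markers: int = 0


@dataclass
class CrossoverInterval:
    """Open interval between the nearest flanking informative markers.

    ``left``/``right`` are reference (genome-A) marker positions; the
    exchange occurred strictly between them. ``width`` counts the bases
    strictly between the bounds.
    """

    left: int
    right: int
    width: int
    wraps_origin: bool
    left_marker: int
    right_marker: int
    upstream_origin: str = ""
    downstream_origin: str = ""


@dataclass
class SegmentMap:
    """Circular painting of one recombinant line against the reference parent."""

    line: str
    reference: str
    length: int  # reference circle length
    segments: list[Segment]
    heteroplasmic_regions: list[tuple[int, int]] = field(default_factory=list)
    de_novo_sites: list[int] = field(default_factory=list)
    isolated_discordant: list[tuple[int, str]] = field(default_factory=list)
    open_ended: bool = False

    @property
    def n_crossovers(self) -> int:
        return 0 if len(self.segments) <= 1 else len(self.segments)


def segment_origins(calls: list[OriginCall], markers: list[Marker],
                    line: str = "", reference: str = "", length: int = 0,
                    min_run: int = 2,
                    include_masked: bool = False) -> SegmentMap:
    """Collapse origin calls into a circular segment map.

    Calls are taken in circular marker order. Masked-region markers are
    excluded unless ``include_masked``; DE_NOVO and MISSING calls never
    contribute. A run of fewer than ``min_run`` discordant calls flanked on
    both sides by the same origin does not break the segment (guard against
    isolated sequencing error / gene conversion); it is listed in
    ``isolated_discordant``. HETEROPLASMIC runs of at least ``min_run``
    become heteroplasmic regions rather than segment breaks.
    """
    by_id = {m.id: m for m in markers}
    order = sorted(range(len(calls)),
                   key=lambda i: by_id[calls[i].marker_id].col_start)
    usable: list[tuple[int, str]] = []  # (marker id, state) circular order
    de_novo: list[int] = []
    het: list[int] = []
    for i in order:
        call = calls[i]
        mk = by_id[call.marker_id]
        if mk.in_masked_region and not include_masked:
            continue
        if call.state == MISSING:
            continue
        if call.state == DE_NOVO:
            de_novo.append(mk.pos_a)
            continue
        usable.append((mk.id, call.state))
    if not any(st in (P1, P2) for _, st in usable):
        raise ValueError(f"{line or 'line'}: no usable P1/P2 origin calls")

    # collapse into circular runs of equal state
    runs: list[list[tuple[int, str]]] = []
    for mid, st in usable:
        if runs and runs[-1][0][1] == st:
            runs[-1].append((mid, st))
        else:
            runs.append([(mid, st)])
    if len(runs) > 1 and runs[0][0][1] == runs[-1][0][1]:
        runs[-1].extend(runs[0])
        runs.pop(0)

    # heteroplasmic runs: long ones become regions, short ones are dropped
    het_regions: list[tuple[int, int]] = []
    kept: list[list[tuple[int, str]]] = []
    for run in runs:
        if run[0][1] == HETEROPLASMIC:
            if len(run) >= min_run:
                het_regions.append((by_id[run[0][0]].pos_a,
                                    by_id[run[-1][0]].pos_a))
        else:
            kept.append(run)
    # removing heteroplasmic runs can leave same-origin neighbours: re-collapse
    runs = []
    for run in kept:
        if runs and runs[-1][0][1] == run[0][1]:
            runs[-1].extend(run)
        else:
            runs.append(run)
    if len(runs) > 1 and runs[0][0][1] == runs[-1][0][1]:
        runs[-1].extend(runs[0])
        runs.pop(0)

    # absorb sub-min_run discordant runs flanked by a single other origin
    isolated: list[tuple[int, str]] = []
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, run in enumerate(runs):
            if len(run) >= min_run or len(runs) == 1:
                continue
            prev_run = runs[(i - 1) % len(runs)]
            next_run = runs[(i + 1) % len(runs)]
            if prev_run is next_run:
                # two-run circle: drop the short run, keep the long one
                if len(prev_run) >= min_run:
                    isolated.extend((by_id[mid].pos_a, st) for mid, st in run)
                    runs = [prev_run]
                    changed = True
                    break
                continue
            if prev_run[0][1] != next_run[0][1]:
                continue
            isolated.extend((by_id[mid].pos_a, st) for mid, st in run)
            merged = prev_run + next_run
            if i == 0:
                runs = [merged] + runs[2:-1]
            elif i == len(runs) - 1:
                runs = runs[1:i - 1] + [merged]
            else:
                runs = runs[:i - 1] + [merged] + runs[i + 2:]
            changed = True
            break

    segments = [Segment(
        origin=run[0][1], first_marker=run[0][0], last_marker=run[-1][0],
        start=by_id[run[0][0]].pos_a, end=by_id[run[-1][0]].pos_a,
        n_markers=len(run)) for run in runs]
    return SegmentMap(line=line, reference=reference, length=length,
                      segments=segments, heteroplasmic_regions=het_regions,
                      de_novo_sites=de_novo, isolated_discordant=isolated)


def crossover_intervals(segmap: SegmentMap,
                        markers: list[Marker]) -> list[CrossoverInterval]:
    """One open interval per adjacent segment pair around the circle."""
    segs = segmap.segments
    if len(segs) < 2:
        return []
    n = segmap.length
    out = []
    for i, seg in enumerate(segs):
        nxt = segs[(i + 1) % len(segs)]
        left, right = seg.end, nxt.start
        width = (right - left - 1) % n
        out.append(CrossoverInterval(
            left=left, right=right, width=width, wraps_origin=right < left,
            left_marker=seg.last_marker, right_marker=nxt.first_marker,
            upstream_origin=seg.origin, downstream_origin=nxt.origin))
    return out


def chimera_composition(segmap: SegmentMap) -> dict[str, float]:
    """Fraction of the reference circle contributed by each parent.

    Each crossover interval's width is split at its midpoint between the
    two flanking origins, so the fractions sum to 1. (Heteroplasmic regions
    sit inside crossover gaps between usable markers and are therefore
    apportioned by the same midpoint rule, not attributed to either parent
    outright.)
    """
    segs = segmap.segments
    n = segmap.length
    share = {P1: 0.0, P2: 0.0}
    if len(segs) == 1:
        share[segs[0].origin] = 1.0
        return share
    for i, seg in enumerate(segs):
        arc = (seg.end - seg.start) % n + 1
        share[seg.origin] += arc
        nxt = segs[(i + 1) % len(segs)]
        gap = (nxt.start - seg.end - 1) % n
        share[seg.origin] += gap / 2.0
        share[nxt.origin] += gap / 2.0
    return {k: v / n for k, v in share.items()}


def at_region_origin(recomb: CircularGenome, ga: CircularGenome,
                     gb: CircularGenome, threshold: int = 500) -> str:
    """Infer which parent donated the length-polymorphic AT-rich region.

    Internal markers are unreliable inside the low-complexity control
    region, but its copy-number length difference shows up in total genome
    length, so the donor is whichever parent's total length is closer to
    the recombinant's — mirroring fragment-length genotyping on a blot.
    Returns "P1", "P2" or "undetermined".
    """
    if abs(len(ga) - len(gb)) < threshold:
        return "undetermined"
    da, db = abs(len(recomb) - len(ga)), abs(len(recomb) - len(gb))
    if abs(da - db) < threshold / 2:
        return "undetermined"
    return P1 if da < db else P2


def segments_bed(segmap: SegmentMap) -> str:
    """Segment map as BED (0-based half-open); wrapping segments split in two."""
    lines = []
    n = segmap.length
    for seg in segmap.segments:
        spans = ([(seg.start - 1, seg.end)] if seg.start <= seg.end
                 else [(seg.start - 1, n), (0, seg.end)])
        for s0, e0 in spans:
            lines.append(f"{segmap.reference}\t{s0}\t{e0}\t{seg.origin}")
    return "\n".join(lines) + "\n"


def segmap_report(segmap: SegmentMap, intervals: list[CrossoverInterval],
                  composition: dict[str, float] | None = None,
                  at_origin: str | None = None) -> dict:
    """JSON-ready report with 1-based mtN coordinates."""
    return {
        "line": segmap.line,
        "reference": segmap.reference,
        "reference_length": segmap.length,
        "n_crossovers": segmap.n_crossovers,
        "segments": [{
            "origin": s.origin, "start": s.start, "end": s.end,
            "first_marker": s.first_marker, "last_marker": s.last_marker,
            "n_markers": s.n_markers,
        } for s in segmap.segments],
        "crossover_intervals": [{
            "left": iv.left, "right": iv.right, "width": iv.width,
            "wraps_origin": iv.wraps_origin,
            "from_origin": iv.upstream_origin, "to_origin": iv.downstream_origin,
        } for iv in intervals],
        "heteroplasmic_regions": [
            {"start": s, "end": e} for s, e in segmap.heteroplasmic_regions],
        "de_novo_sites": list(segmap.de_novo_sites),
        "isolated_discordant": [
            {"pos": p, "state": s} for p, s in segmap.isolated_discordant],
        "composition": composition,
        "at_region_origin": at_origin,
    }
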