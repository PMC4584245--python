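"""Localizing a selectable trait by intersecting donor-origin segments.

A trait carried by one parent (the donor) and scored across recombinant
lines must lie in sequence that every trait-positive line inherited from
the donor and that no trait-negative line did. Candidate intervals are the
intersection of the positives' donor territory minus the union of the
negatives'. Crossover intervals have ambiguous origin, so they count as
donor territory for positive lines but not for negative ones — the
conservative choice that can only widen candidates, never falsely exclude
the causal site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .breakpoint_mapping import CrossoverInterval, SegmentMap
from .marker_calling import Marker


@dataclass
class PhenotypedLine:
    """A recombinant line with its painting and its scored phenotype."""

    name: str
    segmap: SegmentMap
    intervals: list[CrossoverInterval]
    phenotype: str  # "positive" | "negative" | "unknown"
    at_region: tuple[int, int] | None = None  # reference coords of AT region
    at_origin: str | None = None  # P1|P2|undetermined


@dataclass
class TraitMap:
    reference: str
    length: int
    donor: str
    candidates: list[tuple[int, int]]  # 1-based inclusive, may wrap
    marker_ids: list[int]
    supporting_lines: list[str]
    excluding_lines: list[str]

    @property
    def empty(self) -> bool:
        return not self.candidates


def _mark_arc(mask: np.ndarray, start: int, end: int) -> None:
    """Set the circular 1-based inclusive arc start..end to True."""
    n = len(mask)
    if start <= end:
        mask[start - 1:end] = True
    else:
        mask[start - 1:] = True
        mask[:end] = True


def territory(line: PhenotypedLine, donor: str, length: int,
              inclusive: bool) -> np.ndarray:
    """Boolean per-base donor territory of one line.

    ``inclusive`` adds the flanking crossover intervals (ambiguous origin)
    and is used for trait-positive lines; negatives use the definite
    (segment-only) territory.
    """
    mask = np.zeros(length, bool)
    segs = line.segmap.segments
    if len(segs) == 1:
        # pure-parent painting: no crossover anywhere, the whole circle has
        # one origin
        if segs[0].origin == donor:
            mask[:] = True
        return mask
    for seg in segs:
        if seg.origin == donor:
            _mark_arc(mask, seg.start, seg.end)
    if inclusive:
        for iv in line.intervals:
            if donor in (iv.upstream_origin, iv.downstream_origin) and iv.width:
                left1 = iv.left % length + 1
                right1 = (iv.right - 2) % length + 1
                _mark_arc(mask, left1, right1)
    if line.at_region is not None and line.at_origin == donor:
        _mark_arc(mask, *line.at_region)
    return mask


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Circular boolean mask -> 1-based inclusive intervals (wrap merged)."""
    n = len(mask)
    if mask.all():
        return [(1, n)]
    if not mask.any():
        return []
    edges = np.nonzero(np.diff(mask.astype(np.int8)))[0]
    starts = [int(e) + 2 for e in edges if not mask[e]]
    ends = [int(e) + 1 for e in edges if mask[e]]
    if mask[0]:
        starts = [1] + starts  # placeholder, fixed below if wrapping
    if mask[-1]:
        ends = ends + [n]
    ivs = sorted(zip(starts, sorted(ends)))
    ivs = [list(t) for t in ivs]
    if mask[0] and mask[-1] and len(ivs) > 1:
        ivs[-1][1] = ivs[0][1]
        ivs.pop(0)
    return [tuple(t) for t in ivs]


def map_trait(lines: list[PhenotypedLine], donor: str = "P2",
              markers: list[Marker] | None = None,
              reference: str = "", length: int | None = None) -> TraitMap:
    """Intersect donor-origin territory across phenotyped lines.

    Requires at least one trait-positive line; a line name appearing with
    contradictory phenotypes is rejected.
    """
    seen: dict[str, str] = {}
    for ln in lines:
        if ln.name in seen and seen[ln.name] != ln.phenotype:
            raise ValueError(f"line {ln.name} has contradictory phenotypes")
        seen[ln.name] = ln.phenotype
    positives = [ln for ln in lines if ln.phenotype == "positive"]
    negatives = [ln for ln in lines if ln.phenotype == "negative"]
    if not positives:
        raise ValueError("at least one trait-positive line is required")
    if length is None:
        length = positives[0].segmap.length
    mask = np.ones(length, bool)
    for ln in positives:
        mask &= territory(ln, donor, length, inclusive=True)
    for ln in negatives:
        mask &= ~territory(ln, donor, length, inclusive=False)
    candidates = _mask_to_intervals(mask)
    marker_ids = []
    if markers is not None:
        for mk in markers:
            if mask[mk.pos_a - 1]:
                marker_ids.append(mk.id)
    return TraitMap(reference=reference, length=length, donor=donor,
                    candidates=candidates, marker_ids=marker_ids,
                    supporting_lines=[ln.name for ln in positives],
                    excluding_lines=[ln.name for ln in negatives])


def report_trait(tmap: TraitMap, markers: list[Marker] | None = None) -> dict:
    """JSON-ready trait-mapping report."""
    by_id = {m.id: m for m in markers} if markers else {}
    rep = {
        "reference": tmap.reference,
        "reference_length": tmap.length,
        "donor": tmap.donor,
        "no_consistent_interval": tmap.empty,
        "candidates": [{
            "start": s, "end": e,
            "width": (e - s) % tmap.length + 1,
        } for s, e in tmap.candidates],
        "n_markers_inside": len(tmap.marker_ids),
        "markers_inside": [{
            "id": mid,
            **({"posA": by_id[mid].pos_a, "kind": by_id[mid].kind}
               if mid in by_id else {}),
        } for mid in tmap.marker_ids],
        "supporting_lines": tmap.supporting_lines,
        "excluding_lines": tmap.excluding_lines,
    }
    # round-trips through JSON unchanged
    return json.loads(json.dumps(rep))
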