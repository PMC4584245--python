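"""Informative parental markers and parental-origin calls.

A marker is a position where the two parental genomes differ — a SNP at a
mismatch column, or an indel for each maximal gap run of the parental
alignment. Painting a recombinant means aligning it to parent A, projecting
every marker, and classifying the observed allele as P1 (parent A's),
P2 (parent B's), HETEROPLASMIC (an IUPAC code covering both), DE_NOVO
(matching neither), or MISSING (no confident call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circular_alignment import (GAP, AlignmentParams, GenomeAlignment, align)
from .genome_io import IUPAC, CircularGenome

log = logging.getLogger(__name__)

P1 = "P1"
P2 = "P2"
HETEROPLASMIC = "HETEROPLASMIC"
DE_NOVO = "DE_NOVO"
MISSING = "MISSING"

_MASK_CHAR = {}
for _c, _s in IUPAC.items():
    _MASK_CHAR[sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in _s)] = _c


@dataclass
class Marker:
    """One informative parental difference.

    ``pos_a``/``pos_b`` locate the difference on each parent: for a SNP,
    the substituted base; for a deletion (present in A, absent in B), the
    first deleted base on A; for an insertion (absent in A), the base on A
    immediately left of the inserted material. ``a_left``/``a_right`` are
    the nearest genome-A coordinates flanking the difference, and
    ``col_start``/``col_end`` its alignment-column span.
    """

    id: int
    kind: str  # "SNP" | "insertion" | "deletion"
    pos_a: int
    pos_b: int
    allele_a: str
    allele_b: str
    in_masked_region: bool
    a_left: int
    a_right: int
    col_start: int
    col_end: int

    @property
    def length(self) -> int:
        return max(len(self.allele_a), len(self.allele_b))


@dataclass
class OriginCall:
    """A recombinant's parental-origin state at one marker."""

    marker_id: int
    state: str
    observed: str


def call_markers(aln: GenomeAlignment) -> list[Marker]:
    """Derive the informative-marker list from a parental alignment.

    One SNP marker per incompatible-base column, one indel marker per
    maximal gap run (consecutive gap columns collapse). Markers are
    returned in alignment-column (circular) order; markers inside the
    flagged low-complexity region carry ``in_masked_region=True``.
    """
    markers: list[Marker] = []
    a_pos, b_pos = aln.a_pos, aln.b_pos
    a_bit, b_bit = aln.a_base, aln.b_base
    ncol = len(aln)
    la, lb = aln.length_a, aln.length_b

    def prev_nongap(arr, c):
        for k in range(c - 1, c - 1 - ncol, -1):
            if arr[k % ncol] != GAP:
                return int(arr[k % ncol])
        return 0

    c = 0
    while c < ncol:
        if a_pos[c] != GAP and b_pos[c] != GAP:
            if (a_bit[c] & b_bit[c]) == 0:
                pa = int(a_pos[c])
                markers.append(Marker(
                    id=len(markers), kind="SNP", pos_a=pa, pos_b=int(b_pos[c]),
                    allele_a=_MASK_CHAR[int(a_bit[c])],
                    allele_b=_MASK_CHAR[int(b_bit[c])],
                    in_masked_region=bool(aln.masked[c]),
                    a_left=(pa - 2) % la + 1, a_right=pa % la + 1,
                    col_start=c, col_end=c))
            c += 1
            continue
        gap_in_b = b_pos[c] == GAP
        start = c
        while c < ncol and ((b_pos[c] == GAP) if gap_in_b else (a_pos[c] == GAP)):
            c += 1
        end = c - 1
        masked = bool(aln.masked[start:end + 1].any())
        if gap_in_b:  # deletion: A has bases, B does not
            seg = "".join(_MASK_CHAR[int(x)] for x in a_bit[start:end + 1])
            pa1, pa2 = int(a_pos[start]), int(a_pos[end])
            markers.append(Marker(
                id=len(markers), kind="deletion", pos_a=pa1,
                pos_b=prev_nongap(b_pos, start), allele_a=seg, allele_b="",
                in_masked_region=masked,
                a_left=(pa1 - 2) % la + 1, a_right=pa2 % la + 1,
                col_start=start, col_end=end))
        else:  # insertion: B has extra bases between two A positions
            seg = "".join(_MASK_CHAR[int(x)] for x in b_bit[start:end + 1])
            left_a = prev_nongap(a_pos, start)
            markers.append(Marker(
                id=len(markers), kind="insertion", pos_a=left_a,
                pos_b=int(b_pos[start]), allele_a="", allele_b=seg,
                in_masked_region=masked,
                a_left=left_a, a_right=left_a % la + 1,
                col_start=start, col_end=end))
    return markers


def _flanks_match(aln: GenomeAlignment, a_left: int, a_right: int,
                  flank: int) -> bool:
    """Exact (non-gap, identical-base) match over `flank` columns outward of
    the anchor positions on both sides."""
    la = aln.length_a
    match = aln.match_cols
    for step in range(flank):
        pos = (a_left - 1 - step) % la + 1
        c = aln.col_of_a(pos)
        if c < 0 or not match[c]:
            return False
        pos = (a_right - 1 + step) % la + 1
        c = aln.col_of_a(pos)
        if c < 0 or not match[c]:
            return False
    return True


def _segment_between(aln: GenomeAlignment, a_left: int, a_right: int) -> str | None:
    """Recombinant (B-side) bases strictly between two anchored A positions.

    Returns None if either anchor projects to a gap.
    """
    cl = aln.col_of_a(a_left)
    cr = aln.col_of_a(a_right)
    if aln.b_pos[cl] == GAP or aln.b_pos[cr] == GAP:
        return None
    ncol = len(aln)
    out = []
    c = (cl + 1) % ncol
    while c != cr:
        if aln.b_pos[c] != GAP:
            out.append(_MASK_CHAR[int(aln.b_base[c])])
        c = (c + 1) % ncol
    return "".join(out)


def paint_recombinant(recomb: CircularGenome, ga: CircularGenome,
                      gb: CircularGenome, markers: list[Marker],
                      params: AlignmentParams | None = None,
                      indel_flank: int = 10,
                      aln_ra: GenomeAlignment | None = None) -> list[OriginCall]:
    """Call the recombinant's parental-origin state at every marker.

    The recombinant is aligned to parent A and each marker is inspected in
    that alignment. Indel markers are only called when the recombinant
    matches parent A exactly over ``indel_flank`` bases on both sides of
    the indel (indel placement inside low-complexity DNA depends on the
    alignment dialect, so poorly anchored indels are left MISSING).

    A pre-computed parent-A/recombinant alignment can be passed as
    ``aln_ra`` (with the recombinant on the B side) to skip realignment.
    """
    params = params or AlignmentParams()
    if aln_ra is None:
        aln_ra = align(ga, recomb, params)
    calls: list[OriginCall] = []
    for mk in markers:
        calls.append(_call_one(aln_ra, mk, indel_flank))
    run = 0
    for call in calls:
        run = run + 1 if call.state == DE_NOVO else 0
        if run == 3:
            log.warning(
                "%s: >=3 consecutive DE_NOVO calls — possible contamination "
                "or wrong parental pair", recomb.name)
    return calls


def _call_one(aln: GenomeAlignment, mk: Marker, indel_flank: int) -> OriginCall:
    if mk.kind == "SNP":
        c = aln.col_of_a(mk.pos_a)
        if aln.b_pos[c] == GAP:
            return OriginCall(mk.id, MISSING, "")
        obs = _MASK_CHAR[int(aln.b_base[c])]
        exp = IUPAC[obs]
        if obs == mk.allele_a:
            return OriginCall(mk.id, P1, obs)
        if obs == mk.allele_b:
            return OriginCall(mk.id, P2, obs)
        if mk.allele_a in exp and mk.allele_b in exp:
            return OriginCall(mk.id, HETEROPLASMIC, obs)
        return OriginCall(mk.id, DE_NOVO, obs)
    # indel
    if not _flanks_match(aln, mk.a_left, mk.a_right, indel_flank):
        return OriginCall(mk.id, MISSING, "")
    seg = _segment_between(aln, mk.a_left, mk.a_right)
    if seg is None:
        return OriginCall(mk.id, MISSING, "")
    if seg == mk.allele_a:
        return OriginCall(mk.id, P1, seg)
    if seg == mk.allele_b:
        return OriginCall(mk.id, P2, seg)
    return OriginCall(mk.id, DE_NOVO, seg)


def markers_frame(markers: list[Marker]):
    """Markers as a DataFrame sorted by genome-A position."""
    import pandas as pd

    df = pd.DataFrame([{
        "id": m.id, "kind": m.kind, "posA": m.pos_a, "posB": m.pos_b,
        "alleleA": m.allele_a, "alleleB": m.allele_b,
        "masked": m.in_masked_region,
    } for m in markers])
    return df.sort_values("posA").reset_index(drop=True)


def calls_frame(line: str, calls: list[OriginCall]):
    import pandas as pd

    return pd.DataFrame([{
        "line": line, "marker_id": c.marker_id, "state": c.state,
        "observed": c.observed,
    } for c in calls])
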