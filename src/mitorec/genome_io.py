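"""Circular genome I/O, restriction-site location, in-silico digestion.

Coordinates are 1-based inclusive throughout ("mtN" convention: the first
base of the genome is mt1). Circular genomes have no privileged origin, so
every operation here is invariant under rotation of the input sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: IUPAC nucleotide codes -> set of concrete bases they may represent.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

#: Reverse lookup: frozenset of bases -> ambiguity code.
CODE_FOR = {frozenset(v): k for k, v in IUPAC.items()}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CircularGenome:
    """A named (usually circular) DNA sequence.

    ``name`` is the genotype label, e.g. ``"ATP6[1]"`` or
    ``"mt:ND2del1 + mt:CoI T300I"``. ``sequence`` is uppercase DNA over
    {A,C,G,T} plus IUPAC ambiguity codes (used to encode heteroplasmic
    Sanger base calls).
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = next((i for i, c in enumerate(self.sequence) if c not in IUPAC), None)
        if bad is not None:
            raise ValueError(
                f"{self.name}: non-IUPAC character {self.sequence[bad]!r} "
                f"at position {bad + 1}"
            )
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (wraps if circular)."""
        if self.circular:
            return self.sequence[(pos - 1) % len(self.sequence)]
        return self.sequence[pos - 1]

    def subseq(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; wraps around the origin when start > end."""
        if start <= end:
            return self.sequence[start - 1:end]
        if not self.circular:
            raise ValueError("wrapping slice on a linear genome")
        return self.sequence[start - 1:] + self.sequence[:end]

    def rotated(self, offset: int) -> "CircularGenome":
        """New genome whose position 1 is this genome's position offset+1."""
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        off = offset % len(self.sequence)
        return CircularGenome(self.name, self.sequence[off:] + self.sequence[:off])


@dataclass(frozen=True)
class RecognitionSite:
    """A restriction enzyme recognition motif.

    ``cut_offset`` is the number of bases from the motif start to the cut
    position on the top strand (the cut falls between ``start+offset-1`` and
    ``start+offset`` in 1-based coordinates).
    """

    enzyme: str
    motif: str
    cut_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut_offset must lie within the motif")
        if any(c not in "ACGT" for c in self.motif.upper()):
            raise ValueError("motif must be unambiguous DNA")

    @property
    def palindromic(self) -> bool:
        return revcomp(self.motif) == self.motif


# Enzymes used for mtDNA genotyping; all four motifs are palindromic so a
# top-strand scan suffices. Overridable through the run config.
DEFAULT_ENZYMES = {
    "BglII": RecognitionSite("BglII", "AGATCT", 1),
    "XhoI": RecognitionSite("XhoI", "CTCGAG", 1),
    "EcoRI": RecognitionSite("EcoRI", "GAATTC", 1),
    "PstI": RecognitionSite("PstI", "CTGCAG", 5),
}


@dataclass
class DigestResult:
    """Fragments produced by cutting a genome with a set of enzymes.

    Each fragment is ``(start_cut, end_cut, length)`` where the fragment
    spans from just after ``start_cut``'s position to ``end_cut``'s, around
    the circle. For a circular genome with k >= 1 cuts there are exactly k
    fragments whose lengths sum to the genome length; zero cuts leave a
    single uncut circle.
    """

    genome: str
    enzymes: tuple[str, ...]
    fragments: list[tuple[int, int, int]]
    uncut: bool = False
    genome_length: int = 0


def read_genomes(path: str | Path, circular: bool = True,
                 fmt: str | None = None) -> list[CircularGenome]:
    """Read genomes from a FASTA or GenBank file, in file order.

    Ambiguity codes are retained verbatim. Raises ``ValueError`` on an empty
    file or on non-IUPAC characters (the error names the offending 1-based
    position).
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    return [CircularGenome(rec.id, str(rec.seq), circular=circular) for rec in records]


def write_genomes(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.name.replace(" ", "_"), description="")
               for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def find_sites(genome: CircularGenome, site: RecognitionSite) -> list[int]:
    """1-based start positions of motif matches, ascending.

    On a circular genome, matches spanning the origin are found (their start
    position is within 1..length; the match wraps). Linear genomes are
    scanned without wrapping. Ambiguity codes in the genome never match a
    motif: a mixed base call is not assumed to be cut.

    Non-palindromic motifs are scanned on both strands (a bottom-strand hit
    is reported at the top-strand start of its reverse complement).
    """
    motifs = [site.motif]
    if not site.palindromic:
        motifs.append(revcomp(site.motif))
    n, m = len(genome), len(site.motif)
    search_space = genome.sequence + (genome.sequence[:m - 1] if genome.circular else "")
    hits: set[int] = set()
    for motif in motifs:
        start = search_space.find(motif)
        while start != -1:
            if start < n:
                hits.add(start + 1)
            start = search_space.find(motif, start + 1)
    return sorted(hits)


def digest(genome: CircularGenome,
           sites: Sequence[RecognitionSite]) -> DigestResult:
    """Predict restriction fragments of a (circular) genome.

    Cut positions are ``match_start + cut_offset`` taken modulo the genome
    length; fragments run between consecutive cuts around the circle.
    Coinciding cut positions collapse to a single cut (logged).
    """
    n = len(genome)
    cuts: set[int] = set()
    seen = 0
    for site in sites:
        for start in find_sites(genome, site):
            cut = (start - 1 + site.cut_offset) % n  # 0-based gap index after base `cut`
            if cut in cuts:
                log.info("digest(%s): overlapping cut at %d collapsed", genome.name, cut)
            cuts.add(cut)
            seen += 1
    names = tuple(s.enzyme for s in sites)
    if not cuts:
        return DigestResult(genome.name, names, [(1, n, n)], uncut=True, genome_length=n)
    ordered = sorted(cuts)
    fragments = []
    for i, c in enumerate(ordered):
        nxt = ordered[(i + 1) % len(ordered)]
        length = (nxt - c) % n or n  # single cut -> full-length linearized circle
        fragments.append((c + 1, nxt if nxt > 0 else n, length))
    return DigestResult(genome.name, names, fragments, uncut=False, genome_length=n)


def _circ_overlap(a_start: int, a_end: int, b_start: int, b_end: int, n: int) -> bool:
    """Do two 1-based inclusive circular intervals share >= 1 base?"""
    la = (a_end - a_start) % n + 1
    lb = (b_end - b_start) % n + 1
    if la + lb >= n:
        return True
    # linearize: does b start within a, or a start within b?
    return (b_start - a_start) % n < la or (a_start - b_start) % n < lb


def probe_hits(result: DigestResult, probe: tuple[int, int]) -> list[tuple[int, int, int]]:
    """Fragments whose circular interval overlaps the probe interval by >= 1 base.

    ``probe`` is a 1-based inclusive (start, end) interval; it may wrap.
    Mirrors Southern-blot probe hybridization: a fragment is detected iff the
    probe sequence lies at least partly within it.
    """
    n = result.genome_length
    ps, pe = probe
    hits = []
    for frag in result.fragments:
        s, e, _ = frag
        if result.uncut or _circ_overlap(s, e, ps, pe, n):
            hits.append(frag)
    return hits


def genotype_by_sites(genome: CircularGenome,
                      panel: Sequence[RecognitionSite]) -> dict[str, bool]:
    """Presence/absence of each enzyme's site; absence = enzyme resistance.

    A genome lacking both BglII and XhoI sites, for instance, is doubly
    resistant — the signature of a recombinant recovered from double-cut
    selection on two singly-resistant parents.
    """
    return {site.enzyme: bool(find_sites(genome, site)) for site in panel}


def digest_report(results: Iterable[DigestResult],
                  probe: tuple[int, int] | None = None):
    """Digest results as a tidy DataFrame (one row per fragment)."""
    import pandas as pd

    rows = []
    for res in results:
        hits = set(probe_hits(res, probe)) if probe else set()
        for frag in res.fragments:
            rows.append({
                "genome": res.genome,
                "enzymes": "+".join(res.enzymes),
                "start": frag[0],
                "end": frag[1],
                "length": frag[2],
                "uncut": res.uncut,
                "probe_hit": frag in hits,
            })
    return pd.DataFrame(rows)
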