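"""Seeded generators for every pipeline stage.

The generator emulates the study system: two circular mitochondrial
genomes of ~19.5 kb and ~17.9 kb that differ by ~100 SNPs and ~20 short
indels in the coding portion, plus a low-complexity AT-rich control region
built from tandem repeats of two unit types whose copy numbers differ
between the parents (a ~1.6 kb length polymorphism). Recombinants are
built by template-switching between homologous coordinates at planted
crossovers; heteroplasmic Sanger reads are emulated as IUPAC consensus
mixtures; and a minimal one-locus transmission-drive model produces
selection trajectories with an optional germline bottleneck.

Every generator is deterministic given its seed: the same seed reproduces
byte-identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .circular_alignment import AlignmentParams, GenomeAlignment, align, at_rich_mask
from .genome_io import CODE_FOR, IUPAC, CircularGenome

BASES = np.array(list("ACGT"))


@dataclass
class ATRegionSpec:
    """Tandem-repeat control region: two unit types with per-parent copies.

    Defaults give parent A a ~5.0 kb region and parent B ~3.3 kb, a ~1.66
    kb difference of two type-I plus two type-II repeat units.
    """

    unit1_length: int = 420
    unit2_length: int = 410
    copies_a: tuple[int, int] = (6, 6)
    copies_b: tuple[int, int] = (4, 4)
    at_fraction: float = 0.94

    def length(self, parent: str) -> int:
        c1, c2 = self.copies_a if parent == "A" else self.copies_b
        return c1 * self.unit1_length + c2 * self.unit2_length


@dataclass
class PlantedMarker:
    kind: str  # SNP | insertion | deletion
    pos_a: int  # on parent A; for insertion: base left of the insert
    allele_a: str
    allele_b: str


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    seed: int
    length_a: int = 0
    length_b: int = 0
    coding_length: int = 0
    at_region_a: tuple[int, int] = (0, 0)
    markers: list[PlantedMarker] = field(default_factory=list)
    crossovers: dict[str, list[int]] = field(default_factory=dict)
    at_donor: dict[str, str] = field(default_factory=dict)
    mixtures: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return asdict(self)


def _random_dna(rng: np.random.Generator, n: int, p_at: float = 0.70) -> str:
    probs = [p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2]
    return "".join(BASES[rng.choice(4, size=n, p=probs)])


def _pick_positions(rng: np.random.Generator, count: int, lo: int, hi: int,
                    min_gap: int) -> np.ndarray:
    """`count` sorted positions in [lo, hi] pairwise at least min_gap apart."""
    span = hi - lo - (count - 1) * min_gap
    if span < count:
        raise ValueError("infeasible marker density for this length")
    raw = np.sort(rng.choice(span, size=count, replace=False))
    return raw + lo + np.arange(count) * min_gap


def simulate_parent_pair(coding_length: int = 14_500, snp_count: int = 100,
                         indel_count: int = 20,
                         at_spec: ATRegionSpec | None = None,
                         seed: int = 0, min_gap: int = 25,
                         max_indel: int = 10
                         ) -> tuple[CircularGenome, CircularGenome, SimTruth]:
    """Two circular parental genomes differing by planted SNPs and indels.

    The coding portion occupies positions 1..coding_length of parent A and
    the AT-rich region the remainder. All planted differences fall in the
    coding portion, at least ``min_gap`` bases apart and away from the
    ends; indel placements are rejection-sampled to be shift-unambiguous
    so each planted event is recovered at exactly its planted coordinate.
    """
    at_spec = at_spec or ATRegionSpec()
    rng = np.random.default_rng(seed)
    coding = _random_dna(rng, coding_length)
    unit1 = _random_dna(rng, at_spec.unit1_length, at_spec.at_fraction)
    unit2 = _random_dna(rng, at_spec.unit2_length, at_spec.at_fraction)
    at_a = unit1 * at_spec.copies_a[0] + unit2 * at_spec.copies_a[1]
    at_b = unit1 * at_spec.copies_b[0] + unit2 * at_spec.copies_b[1]

    truth = SimTruth(seed=seed, coding_length=coding_length)
    n_events = snp_count + indel_count
    margin = 60
    positions = _pick_positions(rng, n_events, margin,
                                coding_length - margin, min_gap)
    kinds = np.array(["SNP"] * snp_count
                     + ["indel"] * indel_count)
    rng.shuffle(kinds)

    seq_a = list(coding)
    parts_b: list[str] = []
    cursor = 0  # 0-based index into coding
    for pos, kind in zip(positions, kinds):
        p = int(pos) - 1  # 0-based
        if kind == "SNP":
            ref = coding[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            parts_b.append(coding[cursor:p])
            parts_b.append(alt)
            cursor = p + 1
            truth.markers.append(PlantedMarker("SNP", p + 1, ref, alt))
        else:
            ln = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # deletion in B of A's bases p..p+ln-1
                # nudge right until the deleted segment cannot shift
                # (keeps its recovered coordinate unambiguous); the nudge is
                # well below min_gap so events never collide
                for _ in range(12):
                    if coding[p - 1] != coding[p + ln - 1] and \
                            coding[p] != coding[p + ln]:
                        break
                    p += 1
                parts_b.append(coding[cursor:p])
                cursor = p + ln
                truth.markers.append(
                    PlantedMarker("deletion", p + 1, coding[p:p + ln], ""))
            else:  # insertion in B between A bases p and p+1
                for _ in range(50):
                    ins = _random_dna(rng, ln)
                    if ins[-1] != coding[p] and ins[0] != coding[p + 1]:
                        break
                parts_b.append(coding[cursor:p + 1])
                parts_b.append(ins)
                cursor = p + 1
                truth.markers.append(PlantedMarker("insertion", p + 1, "", ins))
    parts_b.append(coding[cursor:])
    coding_b = "".join(parts_b)

    ga = CircularGenome("parentA", coding + at_a)
    gb = CircularGenome("parentB", coding_b + at_b)
    truth.length_a = len(ga)
    truth.length_b = len(gb)
    truth.at_region_a = (coding_length + 1, len(ga))
    return ga, gb, truth


def simulate_recombinant(ga: CircularGenome, gb: CircularGenome,
                         crossovers: list[int], truth: SimTruth,
                         aln: GenomeAlignment | None = None,
                         name: str = "recombinant",
                         first_origin: str = "A") -> CircularGenome:
    """Chimeric genome switching template at each crossover.

    ``crossovers`` are parent-A coordinates (even count, >= 2, distinct,
    each at an alignment match column): the chimera follows one parent up
    to and including each crossover base, then switches to the homologous
    coordinate of the other parent. The segment containing position mt1
    (and hence the control region at the end of the map) comes from
    ``first_origin``.
    """
    if len(crossovers) < 2 or len(crossovers) % 2:
        raise ValueError("a circular chimera needs an even number (>= 2) "
                         "of crossovers")
    if len(set(crossovers)) != len(crossovers):
        raise ValueError("crossover positions must be distinct")
    cuts = sorted(int(c) for c in crossovers)
    if aln is None:
        aln = align(ga, gb)
    proj = [aln.project(c) for c in cuts]
    if any(p is None for p in proj):
        raise ValueError("crossover positions must project to both parents "
                         "(choose match columns)")
    seq = []
    origin = first_origin
    bounds_a = [0] + cuts + [len(ga)]
    for i in range(len(bounds_a) - 1):
        a0, a1 = bounds_a[i], bounds_a[i + 1]
        if origin == "A":
            seq.append(ga.sequence[a0:a1])
        else:
            b0 = proj[i - 1] if i > 0 else 0
            b1 = proj[i] if i < len(cuts) else len(gb)
            seq.append(gb.sequence[b0:b1])
        origin = "B" if origin == "A" else "A"
    # even crossover count returns to first_origin for the wrap segment
    truth.crossovers[name] = cuts
    truth.at_donor[name] = first_origin
    return CircularGenome(name, "".join(seq))


def simulate_sanger_mix(genomes: list[CircularGenome],
                        proportions: list[float],
                        minor_threshold: float = 0.10,
                        params: AlignmentParams | None = None,
                        name: str = "mixture") -> CircularGenome:
    """IUPAC consensus of a heteroplasmic mixture, on the coordinates of the
    first genome.

    At each reference position, bases carried by genotypes whose summed
    proportion reaches ``minor_threshold`` are collected; if more than one
    such base exists the position becomes the IUPAC code of their union,
    otherwise the majority base. Gaps cannot be encoded by an ambiguity
    code, so indel positions take the majority state.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if max(proportions) < minor_threshold:
        raise ValueError("all proportions below the minor threshold")
    ref = genomes[0]
    n = len(ref)
    weights: list[dict[str, float]] = [dict() for _ in range(n)]
    for g, prop in zip(genomes, proportions):
        if g is ref or g.sequence == ref.sequence:
            proj_base = list(ref.sequence)
        else:
            aln = align(ref, g, params)
            proj_base = [""] * n
            for c in range(len(aln)):
                if aln.a_pos[c] != 0:
                    b = int(aln.b_base[c])
                    proj_base[aln.a_pos[c] - 1] = \
                        "" if b == 0 else _bit_char(b)
        for i, base in enumerate(proj_base):
            if base:
                for concrete in IUPAC[base]:
                    weights[i][concrete] = (weights[i].get(concrete, 0.0)
                                            + prop / len(IUPAC[base]))
    out = []
    for i, wt in enumerate(weights):
        if not wt:
            out.append(ref.sequence[i])
            continue
        sig = sorted(b for b, p in wt.items() if p >= minor_threshold)
        if len(sig) >= 2:
            out.append(CODE_FOR[frozenset(sig)])
        else:
            out.append(max(wt.items(), key=lambda kv: (kv[1], kv[0]))[0])
    return CircularGenome(name, "".join(out))


def _bit_char(bit: int) -> str:
    from .marker_calling import _MASK_CHAR
    return _MASK_CHAR[bit]


@dataclass
class TrajectoryParams:
    """Minimal one-locus transmission-drive model.

    ``p0``: initial frequency of the driving genotype; ``w``: its
    per-generation relative transmission advantage; ``n_bottleneck``:
    per-generation effective genome copy number for binomial resampling
    (0 = deterministic); ``generations``: number of generations to run.
    """

    p0: float = 0.1
    w: float = 2.0
    n_bottleneck: int = 0
    generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.generations < 1:
            raise ValueError("need at least one generation")


def simulate_drive_trajectory(params: TrajectoryParams) -> np.ndarray:
    """Per-generation frequencies p_0..p_G of the driving genotype.

    Deterministic update p <- w p / (w p + (1 - p)); with a bottleneck,
    binomial resampling of N genome copies follows selection each
    generation.
    """
    rng = np.random.default_rng(params.seed)
    p = params.p0
    out = [p]
    for _ in range(params.generations):
        p = params.w * p / (params.w * p + (1.0 - p))
        if params.n_bottleneck > 0:
            p = rng.binomial(params.n_bottleneck, p) / params.n_bottleneck
        out.append(p)
    return np.array(out)


def trajectory_frame(freqs: np.ndarray):
    import pandas as pd

    return pd.DataFrame({"generation": np.arange(len(freqs)),
                         "frequency": freqs})


def sample_crossover_sites(aln: GenomeAlignment, truth: SimTruth,
                           n_crossovers: int, rng: np.random.Generator,
                           min_separation: int = 300,
                           margin: int = 60) -> list[int]:
    """Draw distinct planted-crossover positions inside the coding region.

    Positions are parent-A coordinates at perfect-match alignment columns
    (so the template switch is between homologous bases), kept away from
    planted markers and from the control-region boundary, and pairwise
    separated by at least ``min_separation``.
    """
    match = aln.match_cols
    ok = np.zeros(truth.length_a + 1, bool)
    apos = aln.a_pos[(aln.a_pos > 0)]
    mcols = match[(aln.a_pos > 0)]
    ok[apos] = mcols
    ok[:margin + 1] = False
    ok[truth.coding_length - margin:] = False
    for mk in truth.markers:
        lo = max(0, mk.pos_a - 3)
        ok[lo:mk.pos_a + len(mk.allele_a) + 3] = False
    candidates = np.nonzero(ok)[0]
    marker_pos = np.array(sorted(m.pos_a for m in truth.markers))

    def every_segment_marked(picks) -> bool:
        # each circular segment between switches must hold >= 1 informative
        # marker, otherwise the chimera is indistinguishable from one with
        # fewer exchanges
        cuts = list(picks) + [picks[0] + truth.length_a]
        return all(
            np.any((marker_pos > lo) & (marker_pos <= hi))
            or np.any((marker_pos + truth.length_a > lo)
                      & (marker_pos + truth.length_a <= hi))
            for lo, hi in zip(cuts, cuts[1:]))

    for _ in range(1000):
        picks = np.sort(rng.choice(candidates, size=n_crossovers,
                                   replace=False))
        if np.diff(picks).min() >= min_separation \
                and every_segment_marked(picks):
            return [int(p) for p in picks]
    raise RuntimeError("could not place separated crossovers")
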