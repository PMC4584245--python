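# Methods

## Problem setting and assumptions

The package analyzes recombination between two circular mitochondrial
genomes ("parent A" and "parent B") of roughly 16–20 kb that are 90–99%
identical in coding sequence, carry indels, and contain one low-complexity
AT-rich control region whose tandem-repeat copy number — and hence total
genome length — can differ between haplotypes by a kilobase or more.
Recombinants are assumed to be chimeras of exactly these two parents
(no third haplotype, no de-novo mutation load beyond isolated sites);
de-novo and contradictory observations are reported rather than modeled.
All coordinates are 1-based inclusive ("mtN"); BED exports convert to
0-based half-open.

## Alignment model

Genome pairs are aligned globally after rotation anchoring: both circles
are rotated so that a longest shared unique exact match (found from
unique shared k-mers, default k = 15, merged into maximal runs; ties break
toward the smallest parent-A coordinate) begins at position 1. This makes
every downstream quantity invariant under the arbitrary sequencing origin.

The alignment itself is an affine-gap global DP (Gotoh three-state
recurrence; gap of length k costs open + k·extend) computed inside a band
around a guide path interpolated through the chained anchors. Scoring
defaults are match +1, mismatch −2, gap open −4, gap extend −1 — chosen
for 90–99% identity mtDNA, favoring a substitution (−2) over a gap pair
(−10) and collapsing adjacent gap columns into single runs. The band
(default half-width 200 bp) doubles whenever the traceback touches a band
edge that is not a matrix boundary, so the reported score equals the
full-matrix optimum; the test suite verifies this against an independent
quadratic-space DP on randomized pairs up to 2 kb. Ties in the DP break
deterministically (diagonal > vertical > horizontal), so identical inputs
give identical alignments. Bases are compared as IUPAC bitmasks: an
ambiguity code "matches" any base in its expansion, which lets
heteroplasmic consensus sequences align without penalty at mixed sites.

Windows of ≥ 90% A+T over 200 bp (circular, overlapping) flag the
control region. Columns there are aligned but masked: tandem-repeat
alignments are dialect-dependent, so masked markers are excluded from
breakpoint mapping by default (config-overridable), and the control
region's parental origin is instead called from total genome length
(donor = parent whose length is nearer, undetermined when parents differ
by < 500 bp or the recombinant is within 250 bp of both).

## Markers and origin painting

One SNP marker per incompatible column; one indel marker per maximal gap
run. For indels the stored position is the first affected parent-A base
(deletion) or the base left of the insert (insertion), with the flanking
match coordinates and column span kept alongside. A recombinant is painted
by aligning it to parent A and reading each marker's column: P1/P2 on
allele match, HETEROPLASMIC when an IUPAC observation covers both parental
alleles, DE_NOVO otherwise, MISSING at gaps. Indel calls additionally
require a 10 bp exact flank match on both sides (the minimum flank the
data would need for an unambiguous placement; the value is this package's
choice, not an empirical constant) and are MISSING otherwise. Three or
more consecutive DE_NOVO calls raise a contamination warning.

## Segments, crossover intervals, composition

Usable calls (P1/P2, unmasked) in circular order collapse into maximal
same-origin runs. A run shorter than `min_run` (default 2) flanked by a
single other origin does not break the segment; its markers are listed as
isolated discordant sites — a guard against isolated base-calling error or
gene conversion, since genuine exchanges in this system span kilobases.
For error-free synthetic panels the tests set `min_run = 1`, which makes
segmentation exactly the minimal-switch explanation of the calls.
HETEROPLASMIC runs of ≥ `min_run` become reported heteroplasmic regions
(bounded by their outermost markers) and do not break segments, mirroring
mixed Sanger signal over part of a circle.

Each adjacent segment pair defines a crossover interval: the open interval
between the last marker of the upstream segment and the first marker of
the downstream one. No usable marker can lie strictly inside it, every
true exchange point must, and a circular map always has an even count.
Chimera composition splits each interval at its midpoint between the two
flanking origins, so fractions sum to 1; heteroplasmic arcs sit inside
those gaps and are therefore apportioned by the same midpoint rule rather
than attributed to either parent outright.

## Junction quantities

Microhomology is measured on the *parental* alignment (the homology the
exchange machinery had available): the maximal run of perfect
(non-gap, identical) columns containing the interval's column span, zero
if an excluded parental difference lies inside the interval. Resection
relative to a restriction cut is the pair of circular distances from the
cut position to the nearer and farther interval bound (minimum 0 when the
cut falls inside the interval). Circular distances always take the shorter
arc, ties toward lower coordinates. Feature proximity is the circular gap
distance (0 when overlapping) from an interval to named annotation
intervals supplied in reference coordinates.

## Trait mapping

Each phenotyped line contributes donor-origin territory as a boolean mask
over the reference circle. Positive lines use the inclusive territory:
donor segments, the open crossover intervals flanking them (origin there
is genuinely ambiguous), and the control region when the length call
assigns it to the donor. Negative lines use only their definite donor
segments. Candidates are the intersection of positive masks minus the
union of negative masks; this asymmetry can only widen candidates, never
falsely exclude the causal site. A line painted as a single segment has no
crossover anywhere, so its territory is the whole circle (or empty). With
few lines the candidate is honestly wide; the report lists the markers
inside it rather than a point estimate.

## Synthetic data: what it emulates, what it does not

`simulate_parent_pair` builds a coding portion (default 14.5 kb, ~70% A+T)
shared between parents except for exactly 100 planted SNPs and 20 planted
indels (1–10 bp, ≥ 25 bp apart, shift-unambiguous by rejection sampling so
every event is recovered at its planted coordinate), followed by a
control region of two tandem-repeat unit types (420 and 410 bp) at 6+6
copies in parent A vs 4+4 in parent B — totals ≈ 19.5 kb vs ≈ 17.8 kb and
a ≈ 1.66 kb length polymorphism. Recombinants template-switch at planted
match-column positions (even count, ≥ 300 bp apart, each segment required
to contain ≥ 1 marker — an undetectable switch is not a usable
observation). Heteroplasmic Sanger reads are emulated as positionwise
IUPAC consensus at a minor-allele threshold (default 10%). The drive model
is one-locus selection p ← w·p/(w·p + 1 − p) with optional binomial
resampling at bottleneck size N (N is a free parameter; no empirical
estimate exists for the germline mtDNA bottleneck here).

The generator does **not** emulate sequencing error, read-level data,
gene conversion tracts, more than two parents, or repeat-unit sequence
divergence inside the control region. Passing tests therefore demonstrate
correctness of the mapping logic at realistic marker densities and
genome scale — not robustness to base-calling noise, which real data
would add and `min_run` exists to absorb.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script — 200 recombinants at
full genome scale, 100 alignment-oracle pairs ≤ 2 kb, 1000 digest cases,
50 trait panels, 500 trajectory replicates — keep a full run around a
minute while exercising every circular edge case (wrapping segments,
wrapping intervals, origin-spanning motifs). All randomness flows from
explicit seeds; reruns are byte-identical. Restriction-site matching is
top-strand for the palindromic default enzymes (BglII, XhoI, EcoRI, PstI)
with a documented both-strand scan for non-palindromic motifs, and IUPAC
ambiguity codes never match a motif (a mixed base is not assumed cut).
Coinciding cut positions collapse to one cut. Degenerate inputs (no shared
anchor k-mer, zero usable calls, contradictory phenotypes, empty feature
lists) raise diagnostics rather than producing silent output.

## Known limitations

- Interval bounds for indel-bounded crossovers use the indel's reference
  position; the few-bp ambiguity of indel placement is below the
  multi-kb scale of the mapped exchanges but is not explicitly propagated.
- Composition near heteroplasmic regions uses the midpoint rule rather
  than a mixture model.
- Partial-coverage recombinants (e.g. coding region only) are handled —
  uncovered markers go MISSING and intervals are computed from the rest —
  but the resulting outermost intervals are only as tight as the covered
  marker span; they are flagged via the line's topology rather than a
  per-interval bound.
- The banded aligner assumes the two genomes are globally colinear
  (no inversions or transpositions), which holds for animal mtDNA
  haplotypes.
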