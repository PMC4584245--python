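"""End-to-end orchestration from a YAML config to a report bundle.

A run takes exactly two parental genomes and any number of recombinant
lines, and produces per line: the informative-marker table, origin calls,
the segment map (BED + JSON), crossover intervals, junction reports,
digest/probe predictions, and — when phenotypes are supplied — the trait
map. Identical inputs and config give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .breakpoint_mapping import (at_region_origin, chimera_composition,
                                 crossover_intervals, segment_origins,
                                 segmap_report, segments_bed)
from .circular_alignment import AlignmentParams, align
from .genome_io import (DEFAULT_ENZYMES, CircularGenome, RecognitionSite,
                        digest, digest_report, find_sites, genotype_by_sites,
                        read_genomes)
from .junction_analysis import junction_report
from .marker_calling import calls_frame, call_markers, markers_frame, paint_recombinant
from .trait_mapping import PhenotypedLine, map_trait, report_trait

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


@dataclass
class RunConfig:
    parents: list[str] = field(default_factory=list)
    recombinants: list[str] = field(default_factory=list)
    enzymes: list[str] = field(default_factory=lambda: ["BglII", "XhoI"])
    custom_enzymes: dict = field(default_factory=dict)
    probe: list[int] | None = None  # [start, end], 1-based inclusive
    cut_enzyme: str | None = None  # enzyme whose parental cut anchors resection
    features: list[dict] = field(default_factory=list)  # {name,start,end}
    phenotypes: dict = field(default_factory=dict)  # line -> positive|negative
    donor: str = "P2"
    alignment: dict = field(default_factory=dict)
    min_run: int = 2
    include_masked: bool = False
    at_length_threshold: int = 500
    outdir: str = "mitorec_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        # parents may be one multi-record file or two single-record files;
        # the record count is enforced after loading
        if not 1 <= len(self.parents) <= 2:
            raise ConfigError("config must name exactly two parental genomes "
                              "(one or two FASTA/GenBank files)")
        for p in [*self.parents, *self.recombinants]:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        for line, ph in self.phenotypes.items():
            if ph not in ("positive", "negative", "unknown"):
                raise ConfigError(f"bad phenotype {ph!r} for line {line!r}")

    def enzyme_panel(self) -> list[RecognitionSite]:
        table = dict(DEFAULT_ENZYMES)
        for name, spec in self.custom_enzymes.items():
            table[name] = RecognitionSite(name, spec["motif"],
                                          spec.get("cut_offset", 1))
        try:
            return [table[name] for name in self.enzymes]
        except KeyError as exc:
            raise ConfigError(f"unknown enzyme {exc.args[0]!r}") from None

    def params(self) -> AlignmentParams:
        return AlignmentParams(**self.alignment)


def _load_single(path: str) -> list[CircularGenome]:
    return read_genomes(path)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the consolidated report dict and
    writes the bundle under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    parents = []
    for p in config.parents:
        recs = stage("read_parents", _load_single, p)
        parents.extend(recs)
    if len(parents) != 2:
        raise ConfigError(f"expected exactly two parents, found {len(parents)}")
    ga, gb = parents
    recombinants: list[CircularGenome] = []
    for p in config.recombinants:
        recombinants.extend(stage("read_recombinants", _load_single, p))

    panel = config.enzyme_panel()
    probe = tuple(config.probe) if config.probe else None
    digests = [stage("digest", digest, g, panel)
               for g in [ga, gb, *recombinants]]
    digest_df = digest_report(digests, probe)
    digest_df.to_csv(outdir / "digests.tsv", sep="\t", index=False)
    genotypes = {g.name: genotype_by_sites(g, panel)
                 for g in [ga, gb, *recombinants]}

    aln = stage("align_parents", align, ga, gb, params)
    markers = stage("call_markers", call_markers, aln)
    markers_frame(markers).to_csv(outdir / "markers.tsv", sep="\t", index=False)

    cut_position = None
    if config.cut_enzyme:
        site = {s.enzyme: s for s in panel}.get(config.cut_enzyme) \
            or DEFAULT_ENZYMES.get(config.cut_enzyme)
        if site is None:
            raise ConfigError(f"unknown cut enzyme {config.cut_enzyme!r}")
        hits = find_sites(ga, site)
        if hits:
            cut_position = (hits[0] - 1 + site.cut_offset) % len(ga) + 1

    features = [(f["name"], int(f["start"]), int(f["end"]))
                for f in config.features]

    lines_report = {}
    phenolines = []
    for rec in recombinants:
        aln_ra = stage("align_recombinant", align, ga, rec, params)
        calls = stage("paint", paint_recombinant, rec, ga, gb, markers,
                      params, aln_ra=aln_ra)
        calls_frame(rec.name, calls).to_csv(
            outdir / f"{_safe(rec.name)}.calls.tsv", sep="\t", index=False)
        segmap = stage("segment", segment_origins, calls, markers,
                       line=rec.name, reference=ga.name, length=len(ga),
                       min_run=config.min_run,
                       include_masked=config.include_masked)
        ivs = crossover_intervals(segmap, markers)
        comp = chimera_composition(segmap)
        at_orig = at_region_origin(rec, ga, gb, config.at_length_threshold)
        (outdir / f"{_safe(rec.name)}.segments.bed").write_text(
            segments_bed(segmap))
        report = segmap_report(segmap, ivs, comp, at_orig)
        if ivs:
            junctions = stage("junctions", junction_report, aln, markers, ivs,
                              cut_position, features or None)
            report["junctions"] = [{
                "interval": {"left": j.interval.left, "right": j.interval.right},
                "microhomology": j.microhomology,
                "resection_min": j.resection_min,
                "resection_max": j.resection_max,
                "markers_between_cut_and_exchange":
                    j.markers_between_cut_and_exchange,
                "nearest_feature": j.nearest_feature,
                "feature_distance": j.feature_distance,
            } for j in junctions]
        report["genotype"] = genotypes[rec.name]
        lines_report[rec.name] = report
        ph = config.phenotypes.get(rec.name, "unknown")
        phenolines.append(PhenotypedLine(
            name=rec.name, segmap=segmap, intervals=ivs, phenotype=ph,
            at_origin=at_orig))

    trait = None
    if any(ln.phenotype == "positive" for ln in phenolines):
        tmap = stage("trait", map_trait, phenolines, donor=config.donor,
                     markers=markers, reference=ga.name, length=len(ga))
        trait = report_trait(tmap, markers)

    bundle = {
        "version": __version__,
        "seed": config.seed,
        "params": vars(params),
        "parents": {"A": ga.name, "B": gb.name,
                    "length_a": len(ga), "length_b": len(gb),
                    "n_markers": len(markers),
                    "identity": aln.percent_identity()},
        "genotypes": genotypes,
        "cut_position": cut_position,
        "lines": lines_report,
        "trait_map": trait,
    }
    (outdir / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=float) + "\n")
    return bundle


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)
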