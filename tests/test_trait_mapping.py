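import json

import numpy as np
import pytest

from mitorec.breakpoint_mapping import (crossover_intervals, segment_origins)
from mitorec.marker_calling import P1, P2, paint_recombinant
from mitorec.trait_mapping import (PhenotypedLine, map_trait, report_trait,
                                   territory)
from mitorec.synthetic_data import (sample_crossover_sites,
                                    simulate_recombinant)

from oracles import bitmap_intersection
from test_breakpoint_mapping import build_map, make_calls, make_markers


def line_from_states(name, positions, states, length, phenotype,
                     at_region=None, at_origin=None):
    segmap, markers = build_map(positions, states, length=length)
    segmap.line = name
    ivs = crossover_intervals(segmap, markers)
    return PhenotypedLine(name=name, segmap=segmap, intervals=ivs,
                          phenotype=phenotype, at_region=at_region,
                          at_origin=at_origin), markers


class TestMapTrait:
    def test_single_fully_donor_line_keeps_whole_genome(self):
        ln, markers = line_from_states("r1", [100, 200, 300],
                                       [P2, P2, P2], 1000, "positive")
        tmap = map_trait([ln], donor=P2, markers=markers, length=1000)
        assert tmap.candidates == [(1, 1000)]
        assert len(tmap.marker_ids) == 3

    def test_negative_line_excludes_its_donor_segments(self):
        pos, markers = line_from_states(
            "r1", [100, 200, 600, 700], [P2, P2, P1, P1], 1000, "positive")
        neg, _ = line_from_states(
            "r2", [100, 200, 600, 700], [P2, P1, P1, P2], 1000, "negative")
        tmap = map_trait([pos, neg], donor=P2, markers=markers, length=1000)
        # r2's definite donor territory (wrap segment 700..100) is excluded;
        # candidate keeps r1's unambiguous donor stretch
        for start, end in tmap.candidates:
            assert not (start <= 100 <= end or start >= 700)
        covered = np.zeros(1000, bool)
        for s, e in tmap.candidates:
            covered[s - 1:e] = True
        assert covered[150 - 1]  # strictly inside r1 donor, outside r2 donor

    def test_monotone_exclusion(self):
        rng = np.random.default_rng(0)
        length = 2000
        positions = sorted(int(p) for p in
                           rng.choice(np.arange(10, 1990), 12, replace=False))
        pos_states = [str(rng.choice([P1, P2])) for _ in positions]
        while len(set(pos_states)) < 2:
            pos_states = [str(rng.choice([P1, P2])) for _ in positions]
        ln, markers = line_from_states("p", positions, pos_states, length,
                                       "positive")
        tmap0 = map_trait([ln], donor=P2, markers=markers, length=length)
        area0 = sum((e - s) % length + 1 for s, e in tmap0.candidates)
        for seed in range(5):
            rng2 = np.random.default_rng(seed + 1)
            neg_states = [str(rng2.choice([P1, P2])) for _ in positions]
            if len(set(neg_states)) < 2:
                continue
            neg, _ = line_from_states("n", positions, neg_states, length,
                                      "negative")
            tmap = map_trait([ln, neg], donor=P2, markers=markers,
                             length=length)
            area = sum((e - s) % length + 1 for s, e in tmap.candidates)
            assert area <= area0

    def test_zero_negatives_equals_bitmap_intersection(self):
        rng = np.random.default_rng(3)
        length = 2000
        lines = []
        markers = None
        for i in range(4):
            positions = sorted(int(p) for p in rng.choice(
                np.arange(10, 1990), 10, replace=False))
            states = [str(rng.choice([P1, P2])) for _ in positions]
            if len(set(states)) < 2:
                states[0] = P1 if states[1] == P2 else P2
            ln, mks = line_from_states(f"l{i}", positions, states, length,
                                       "positive")
            lines.append(ln)
            markers = markers or mks
        tmap = map_trait(lines, donor=P2, markers=markers, length=length)
        masks = [territory(ln, P2, length, inclusive=True) for ln in lines]
        expected = bitmap_intersection(masks, [])
        got = np.zeros(length, bool)
        for s, e in tmap.candidates:
            if s <= e:
                got[s - 1:e] = True
            else:
                got[s - 1:] = True
                got[:e] = True
        assert np.array_equal(got, expected)

    def test_contradictory_phenotypes_rejected(self):
        a, markers = line_from_states("r1", [100, 200], [P2, P2], 500,
                                      "positive")
        b, _ = line_from_states("r1", [100, 200], [P2, P2], 500, "negative")
        with pytest.raises(ValueError, match="contradictory"):
            map_trait([a, b], donor=P2, markers=markers, length=500)

    def test_requires_a_positive_line(self):
        ln, markers = line_from_states("r1", [100, 200], [P2, P2], 500,
                                       "negative")
        with pytest.raises(ValueError, match="positive"):
            map_trait([ln], donor=P2, markers=markers, length=500)


class TestCausalMarkerRecovery:
    @pytest.mark.parametrize("seed", range(8))
    def test_planted_causal_marker_always_in_candidates(self, seed,
                                                        parent_pair,
                                                        parent_aln,
                                                        parent_markers):
        # phenotype = carriage of one planted causal marker allele from the
        # donor parent; candidates must contain it and match the bitmap oracle
        ga, gb, truth = parent_pair
        length = len(ga)
        rng = np.random.default_rng(seed)
        usable = [m for m in parent_markers if not m.in_masked_region]
        causal = usable[int(rng.integers(0, len(usable)))]
        lines = []
        for i in range(8):
            sites = sample_crossover_sites(
                parent_aln, truth, int(rng.choice([2, 4])), rng)
            rec = simulate_recombinant(ga, gb, sites, truth, parent_aln,
                                       name=f"s{seed}r{i}")
            calls = paint_recombinant(rec, ga, gb, parent_markers,
                                      aln_ra=None)
            # error-free synthetic calls: trust single-marker segments
            segmap = segment_origins(calls, parent_markers, line=rec.name,
                                     reference=ga.name, length=length,
                                     min_run=1)
            ivs = crossover_intervals(segmap, parent_markers)
            state = {c.marker_id: c.state for c in calls}
            phenotype = "positive" if state[causal.id] == P2 else "negative"
            lines.append(PhenotypedLine(name=rec.name, segmap=segmap,
                                        intervals=ivs, phenotype=phenotype))
        if not any(ln.phenotype == "positive" for ln in lines):
            pytest.skip("no positive line drawn for this seed")
        tmap = map_trait(lines, donor=P2, markers=parent_markers,
                         length=length)
        assert causal.id in tmap.marker_ids
        positives = [territory(ln, P2, length, True)
                     for ln in lines if ln.phenotype == "positive"]
        negatives = [territory(ln, P2, length, False)
                     for ln in lines if ln.phenotype == "negative"]
        expected = bitmap_intersection(positives, negatives)
        got = np.zeros(length, bool)
        for s, e in tmap.candidates:
            if s <= e:
                got[s - 1:e] = True
            else:
                got[s - 1:] = True
                got[:e] = True
        assert np.array_equal(got, expected)


class TestATRegionScenario:
    def test_drive_region_maps_to_at_region_plus_flanking_snps(
            self, parent_pair, parent_aln, parent_markers):
        # one positive recombinant whose donor segment covers the control
        # region plus a few flanking SNPs; the pure non-donor parent is the
        # negative line: candidates = AT region + flanks
        ga, gb, truth = parent_pair
        length = len(ga)
        usable = sorted((m for m in parent_markers if not m.in_masked_region),
                        key=lambda m: m.pos_a)

        def pick_site(lo, hi):
            for p in range((lo + hi) // 2, hi):
                if parent_aln.project(p) is not None and \
                        all(abs(p - m.pos_a) > 12 for m in parent_markers):
                    return p
            raise AssertionError("no valid switch site")

        # donor wrap segment contains 1 marker at the head, 2 at the tail
        c1 = pick_site(usable[0].pos_a, usable[1].pos_a)
        c2 = pick_site(usable[-3].pos_a, usable[-2].pos_a)
        rec = simulate_recombinant(ga, gb, [c1, c2], truth, parent_aln,
                                   name="drive", first_origin="B")
        calls = paint_recombinant(rec, ga, gb, parent_markers)
        segmap = segment_origins(calls, parent_markers, line="drive",
                                 reference=ga.name, length=length)
        ivs = crossover_intervals(segmap, parent_markers)
        pos_line = PhenotypedLine(
            name="drive", segmap=segmap, intervals=ivs, phenotype="positive",
            at_region=truth.at_region_a, at_origin=P2)
        neg_map, _ = None, None
        neg_calls = paint_recombinant(ga, ga, gb, parent_markers)
        neg_segmap = segment_origins(neg_calls, parent_markers, line="parentA",
                                     reference=ga.name, length=length)
        neg_line = PhenotypedLine(name="parentA", segmap=neg_segmap,
                                  intervals=[], phenotype="negative",
                                  at_region=truth.at_region_a, at_origin=P1)
        tmap = map_trait([pos_line, neg_line], donor=P2,
                         markers=parent_markers, length=length)
        assert len(tmap.candidates) == 1
        (start, end) = tmap.candidates[0]
        covered = np.zeros(length, bool)
        if start <= end:
            covered[start - 1:end] = True
        else:
            covered[start - 1:] = True
            covered[:end] = True
        at_lo, at_hi = truth.at_region_a
        assert covered[at_lo - 1] and covered[at_hi - 1]
        flank_snps = [m for m in usable if covered[m.pos_a - 1]]
        assert len(flank_snps) == 3


class TestReportTrait:
    def test_round_trip_and_empty_record(self, ):
        ln, markers = line_from_states("r1", [100, 200, 600, 700],
                                       [P2, P2, P1, P1], 1000, "positive")
        neg, _ = line_from_states("r2", [100, 200, 600, 700],
                                  [P2, P2, P1, P1], 1000, "negative")
        neg.name = "r2"
        tmap = map_trait([ln, neg], donor=P2, markers=markers, length=1000)
        rep = report_trait(tmap, markers)
        assert rep == json.loads(json.dumps(rep))
        if not tmap.candidates:
            assert rep["no_consistent_interval"]
        single = map_trait([ln], donor=P2, markers=markers, length=1000)
        rep2 = report_trait(single, markers)
        assert rep2["candidates"] and rep2["n_markers_inside"] >= 2
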