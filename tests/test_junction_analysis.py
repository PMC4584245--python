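import numpy as np
import pytest

from mitorec.breakpoint_mapping import CrossoverInterval
from mitorec.circular_alignment import AlignmentParams, align
from mitorec.genome_io import CircularGenome
from mitorec.junction_analysis import (feature_proximity, markers_between,
                                       microhomology, resection_estimate)
from mitorec.marker_calling import call_markers

from conftest import mutate, random_dna
from oracles import circ_dist

NOROT = AlignmentParams(auto_rotate=False, mask_low_complexity=False)


def interval(left, right, n):
    return CrossoverInterval(left=left, right=right,
                             width=(right - left - 1) % n,
                             wraps_origin=right < left,
                             left_marker=0, right_marker=1)


def snp_pair(rng, length, positions):
    """Parents differing by SNPs exactly at the given 1-based positions."""
    sa = random_dna(rng, length)
    sb = list(sa)
    for p in positions:
        sb[p - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sb[p - 1]]
    return CircularGenome("a", sa), CircularGenome("b", "".join(sb))


class TestMicrohomology:
    def test_eleven_base_window_between_mismatches(self):
        # exchange interval inside an 11-column perfect window bounded by
        # mismatches on both sides
        rng = np.random.default_rng(0)
        ga, gb = snp_pair(rng, 600, [300, 312])
        aln = align(ga, gb, NOROT)
        markers = call_markers(aln)
        iv = interval(300, 312, 600)
        iv.left_marker, iv.right_marker = markers[0].id, markers[1].id
        assert microhomology(aln, iv, markers) == 11

    def test_homology_spans_to_other_bounding_markers(self):
        # parents identical except the two bounding markers of a 2-crossover
        # chimera: the perfect run extends around to the other markers
        rng = np.random.default_rng(1)
        ga, gb = snp_pair(rng, 400, [100, 300])
        aln = align(ga, gb, NOROT)
        markers = call_markers(aln)
        iv = interval(100, 300, 400)
        iv.left_marker, iv.right_marker = markers[0].id, markers[1].id
        assert microhomology(aln, iv, markers) == 199  # 101..299

    def test_interval_containing_excluded_difference_scores_zero(self):
        rng = np.random.default_rng(2)
        ga, gb = snp_pair(rng, 500, [200, 250, 300])
        aln = align(ga, gb, NOROT)
        markers = call_markers(aln)
        # interval spanning the middle (excluded) polymorphism at 250
        iv = interval(200, 300, 500)
        iv.left_marker = next(m.id for m in markers if m.pos_a == 200)
        iv.right_marker = next(m.id for m in markers if m.pos_a == 300)
        assert microhomology(aln, iv, markers) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_run_scan(self, seed):
        rng = np.random.default_rng(seed + 50)
        npoly = int(rng.integers(4, 12))
        positions = np.sort(rng.choice(np.arange(20, 480), npoly,
                                       replace=False))
        ga, gb = snp_pair(rng, 500, [int(p) for p in positions])
        aln = align(ga, gb, NOROT)
        markers = call_markers(aln)
        assert len(markers) == npoly
        match = aln.match_cols
        for i in range(len(markers)):
            left, right = markers[i], markers[(i + 1) % len(markers)]
            iv = interval(left.pos_a, right.pos_a, 500)
            iv.left_marker, iv.right_marker = left.id, right.id
            # oracle: walk outward from the interval over match columns
            n = len(aln)
            run = 0
            c = (left.col_end + 1) % n
            while c != right.col_start:
                run += 1
                c = (c + 1) % n
            got = microhomology(aln, iv, markers)
            assert got == run  # bounding diffs stop the extension

    def test_monotone_under_planted_mismatch(self):
        rng = np.random.default_rng(99)
        ga, gb = snp_pair(rng, 600, [300, 340])
        aln = align(ga, gb, NOROT)
        markers = call_markers(aln)
        iv = interval(300, 340, 600)
        iv.left_marker, iv.right_marker = markers[0].id, markers[1].id
        before = microhomology(aln, iv, markers)
        ga2, gb2 = snp_pair(np.random.default_rng(99), 600, [300, 320, 340])
        aln2 = align(ga2, gb2, NOROT)
        mk2 = call_markers(aln2)
        iv2 = interval(300, 340, 600)
        iv2.left_marker = next(m.id for m in mk2 if m.pos_a == 300)
        iv2.right_marker = next(m.id for m in mk2 if m.pos_a == 340)
        assert microhomology(aln2, iv2, mk2) <= before


class TestResectionEstimate:
    def test_printed_range_reconstruction(self):
        # cut at 500 with exchange bounded by markers at 456 and 492
        assert resection_estimate(interval(456, 492, 16000), 500, 16000) \
            == (8, 44)

    def test_cut_inside_interval_min_zero(self):
        lo, hi = resection_estimate(interval(456, 492, 16000), 470, 16000)
        assert lo == 0 and hi == max(circ_dist(470, 456, 16000),
                                     circ_dist(470, 492, 16000))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_distances(self, seed):
        rng = np.random.default_rng(seed)
        n = 10_000
        left = int(rng.integers(1, n + 1))
        right = (left + int(rng.integers(2, 500))) % n + 1
        cut = int(rng.integers(1, n + 1))
        lo, hi = resection_estimate(interval(left, right, n), cut, n)
        dl, dr = circ_dist(cut, left, n), circ_dist(cut, right, n)
        off = (cut - left) % n
        inside = 0 < off < (right - left) % n
        assert hi == max(dl, dr)
        assert lo == (0 if inside else min(dl, dr))

    def test_rotation_invariance(self):
        n = 16000
        base = resection_estimate(interval(456, 492, n), 500, n)
        for off in (100, 8000, 15990):
            shifted = resection_estimate(
                interval((456 + off - 1) % n + 1, (492 + off - 1) % n + 1, n),
                (500 + off - 1) % n + 1, n)
            assert shifted == base


class TestMarkersBetween:
    def _markers(self, positions):
        from test_breakpoint_mapping import make_markers
        return make_markers(positions)

    def test_no_markers_between(self):
        mks = self._markers([100, 200])
        assert markers_between(mks, 500, interval(456, 492, 16000), 16000) == 0

    def test_two_markers_between_cut_and_exchange(self):
        # two SNPs between the exchange interval and the cleavage site
        mks = self._markers([456, 470, 492])
        assert markers_between(mks, 500, interval(456, 492, 16000), 16000) == 2

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_count(self, seed):
        rng = np.random.default_rng(seed + 7)
        n = 5000
        left = int(rng.integers(1, n))
        right = (left + int(rng.integers(2, 200))) % n + 1
        cut = int(rng.integers(1, n + 1))
        pos = sorted(int(p) for p in
                     rng.choice(np.arange(1, n + 1), 30, replace=False))
        mks = self._markers(pos)
        dl, dr = circ_dist(cut, left, n), circ_dist(cut, right, n)
        far = left if dl >= dr else right
        span = min((cut - far) % n, (far - cut) % n)
        expected = 0
        for p in pos:
            d_far = (p - far) % n
            d_cut = (p - cut) % n
            if (cut - far) % n <= (far - cut) % n:
                inside = 0 < d_far < (cut - far) % n
            else:
                inside = 0 < (far - p) % n < (far - cut) % n
            expected += inside
        assert markers_between(mks, cut, interval(left, right, n), n) \
            == expected


class TestFeatureProximity:
    FEATURES = [("DmTTF-1", 6314, 6341), ("DmTTF-2", 11698, 11725)]

    def test_overlapping_feature_distance_zero(self):
        (hit,) = feature_proximity([interval(6320, 6400, 16000)],
                                   self.FEATURES, 16000)
        assert hit == ("DmTTF-1", 0)

    def test_gap_distance_to_nearest_binding_site(self):
        (hit,) = feature_proximity([interval(6200, 6300, 16000)],
                                   self.FEATURES, 16000)
        assert hit == ("DmTTF-1", 14)

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValueError):
            feature_proximity([interval(1, 10, 100)], [], 100)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed + 31)
        n = 8000
        feats = []
        for i in range(4):
            s = int(rng.integers(1, n + 1))
            feats.append((f"f{i}", s, (s + int(rng.integers(5, 100))) % n + 1))
        left = int(rng.integers(1, n + 1))
        right = (left + int(rng.integers(2, 300))) % n + 1
        iv = interval(left, right, n)
        got_name, got_d = feature_proximity([iv], feats, n)[0]

        def points(s, e):
            return [(s - 1 + k) % n + 1 for k in range((e - s) % n + 1)]

        ivp = points(iv.left, iv.right)
        best = min(
            0 if set(ivp) & set(points(fs, fe))
            else min(circ_dist(p, q, n)
                     for p in ivp for q in points(fs, fe))
            for _, fs, fe in feats)
        assert got_d == best
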