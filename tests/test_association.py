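"""Cost fusion, Hungarian matching, candidate window, edge-plant logic."""

import itertools

import numpy as np
import pytest

from rowtrack.association import (IN_VIEW, OUT_OF_VIEW, AssociationConfig,
                                  LibraryEntry, assign_edge_plants,
                                  build_cost_matrices, candidate_window,
                                  estimate_direction, hungarian_match)
from rowtrack.features import PlantFeature, extract_feature
from rowtrack.io import Detection
from rowtrack.motion import iou, kf_initiate


def det(cx, cy, w=80.0, h=80.0, frame=2):
    return Detection(frame=frame, cx=cx, cy=cy, w=w, h=h)


def entry(plant_id, ordinal, cy, lane=0, cx=300.0, status=IN_VIEW,
          feature=None, frame=1):
    box = det(cx, cy, frame=frame)
    return LibraryEntry(plant_id=plant_id, lane=lane, ordinal=ordinal,
                        feature=feature, last_box=box,
                        kstate=kf_initiate(box), last_seen_frame=frame,
                        status=status)


class TestBuildCostMatrices:
    def test_perfect_match_is_matrix_minimum(self):
        f = PlantFeature(1.0, 1.0, 1.0, 1.0)
        e = entry(1, 0, 500, feature=f)
        mats = build_cost_matrices([(det(300, 500), f)], [e])
        assert mats.feat[0, 0] == 0
        assert mats.iou[0, 0] == pytest.approx(1.0)
        assert mats.final[0, 0] == pytest.approx(-1.0)

    def test_out_of_view_candidate_degrades_to_feature_only(self):
        f = PlantFeature(1.0, 1.0, 1.0, 1.0)
        e = entry(1, 0, 500, feature=f, status=OUT_OF_VIEW)
        mats = build_cost_matrices([(det(300, 500), f)], [e])
        assert mats.iou[0, 0] == 0
        assert mats.final[0, 0] == mats.feat[0, 0]

    def test_entries_match_elementwise_recomputation(self):
        rng = np.random.default_rng(4)
        dets, cands = [], []
        for k in range(3):
            cy = 200.0 + 150 * k
            f = PlantFeature(*rng.uniform(0.5, 2, size=4))
            dets.append((det(300 + rng.normal(0, 5), cy + rng.normal(0, 5)), f))
            cands.append(entry(k + 1, k, cy,
                               feature=PlantFeature(*rng.uniform(0.5, 2, size=4))))
        mats = build_cost_matrices(dets, cands)
        from rowtrack.features import feature_distance
        for i, (d, f) in enumerate(dets):
            for j, c in enumerate(cands):
                assert mats.feat[i, j] == pytest.approx(
                    feature_distance(f, c.feature))
                assert mats.iou[i, j] == pytest.approx(
                    iou(d.box, c.kstate.box))
                assert mats.final[i, j] == mats.feat[i, j] - mats.iou[i, j]

    def test_candidate_without_feature_takes_neutral_cost(self):
        e = entry(1, 0, 500, feature=None)
        mats = build_cost_matrices(
            [(det(300, 500), PlantFeature(1, 1, 1, 1))], [e], tau_feat=0.4)
        assert mats.feat[0, 0] == 0.4


class TestHungarianMatch:
    def test_diagonal_optimum(self):
        pairs, _, _ = hungarian_match(np.array([[0.1, 0.9], [0.9, 0.1]]))
        assert pairs == [(0, 0), (1, 1)]

    def test_anti_diagonal_optimum(self):
        pairs, _, _ = hungarian_match(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert pairs == [(0, 1), (1, 0)]

    def test_threshold_demotes_costly_pairs(self):
        pairs, ur, uc = hungarian_match(
            np.array([[0.1, 0.9], [0.9, 0.7]]), tau_final=0.5)
        assert pairs == [(0, 0)]
        assert ur == [1] and uc == [1]

    def test_empty_matrix(self):
        pairs, ur, uc = hungarian_match(np.zeros((0, 3)))
        assert pairs == [] and ur == [] and uc == [0, 1, 2]

    def test_matches_brute_force_permutation_minimum(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            M = rng.uniform(0, 1, size=(n, n))
            pairs, _, _ = hungarian_match(M)
            total = sum(M[r, c] for r, c in pairs)
            best = min(sum(M[i, p[i]] for i in range(n))
                       for p in itertools.permutations(range(n)))
            assert total == pytest.approx(best, abs=1e-12)


class TestCandidateWindow:
    def make_library(self, n=10):
        return [entry(k + 1, k, 100.0 * k) for k in range(n)]

    def test_window_spans_anchor_interval(self):
        lib = self.make_library()
        sel = candidate_window(lib, lib[5], x1=3, x2=2)
        assert [e.ordinal for e in sel] == [2, 3, 4, 5, 6, 7]

    def test_clipped_at_lane_start(self):
        lib = self.make_library()
        sel = candidate_window(lib, lib[0], x1=3, x2=2)
        assert [e.ordinal for e in sel] == [0, 1, 2]

    def test_zero_radius_returns_anchor_only(self):
        lib = self.make_library()
        assert candidate_window(lib, lib[4], 0, 0) == [lib[4]]

    def test_output_is_contiguous_range_intersection(self):
        lib = self.make_library(12)
        present = [lib[i] for i in (0, 2, 3, 7, 8, 11)]
        sel = candidate_window(present, lib[3], x1=2, x2=5)
        assert [e.ordinal for e in sel] == [2, 3, 7, 8]

    def test_raw_id_mode(self):
        lib = self.make_library()
        sel = candidate_window(lib, lib[5], x1=1, x2=1, mode="raw_id")
        assert [e.plant_id for e in sel] == [5, 6, 7]


class TestEstimateDirection:
    def test_uniform_downward_drift(self):
        pairs = [(det(300, y, frame=1), det(300, y + 15)) for y in (100, 300)]
        assert estimate_direction(pairs, eps_dir=2) == "drift_down"

    def test_empty_is_stationary(self):
        assert estimate_direction([], eps_dir=2) == "stationary"

    def test_median_defeats_outlier(self):
        deltas = [15, 14, -200]
        pairs = [(det(300, 500, frame=1), det(300, 500 + d)) for d in deltas]
        assert estimate_direction(pairs, eps_dir=2) == "drift_down"

    def test_dead_band(self):
        pairs = [(det(300, 500, frame=1), det(300, 501))]
        assert estimate_direction(pairs, eps_dir=2) == "stationary"


class TestAssignEdgePlants:
    cfg = AssociationConfig()

    def test_forward_entering_mints_beyond_lane_extent(self):
        # nearest tracked middle is the most advanced plant in the library:
        # the two plants entering at the bottom are genuinely new
        lib = [entry(k + 1, k, 650.0 + 100 * (k - 15),
                     status=IN_VIEW if k >= 15 else OUT_OF_VIEW)
               for k in range(18)]
        a = det(300, 850)  # the plant of ordinal 17 seen as a middle
        tracked = {0: lib[17]}
        dets = [a, det(300, 950), det(300, 1050)]
        ea = assign_edge_plants({"top_edge": [], "bottom_edge": [1, 2]},
                                dets, {1: 0, 2: 0}, lib, "drift_up",
                                tracked, self.cfg, spacing=100.0)
        assert ea.matched == {}
        assert ea.minted == [(1, 0, 18), (2, 0, 19)]

    def test_reverse_entering_reidentifies_library_neighbors(self):
        # after reversing, the library extends far beyond the anchor plant:
        # entering plants are its out-of-view neighbors, not new plants
        lib = [entry(k + 1, k, 100.0 * k,
                     status=OUT_OF_VIEW if k < 15 else IN_VIEW)
               for k in range(30)]
        a = det(300, 250)  # plant of ordinal 15 (ID 16) tracked as middle
        dets = [a, det(300, 150), det(300, 50)]
        tracked = {0: lib[15]}
        ea = assign_edge_plants({"top_edge": [1, 2], "bottom_edge": []},
                                dets, {1: 0, 2: 0}, lib, "drift_down",
                                tracked, self.cfg, spacing=100.0)
        assert ea.minted == []
        assert {i: e.plant_id for i, e in ea.matched.items()} == {1: 15, 2: 14}

    def test_stationary_matches_by_iou_and_never_mints(self):
        lib = [entry(k + 1, k, 100.0 * k + 50) for k in range(4)]
        dets = [det(300, 52), det(300, 351)]
        ea = assign_edge_plants({"top_edge": [0], "bottom_edge": [1]},
                                dets, {0: 0, 1: 0}, lib, "stationary",
                                {}, self.cfg, spacing=100.0)
        assert ea.minted == []
        assert ea.matched[0].plant_id == 1
        assert ea.matched[1].plant_id == 4

    def test_entering_without_anchor_is_deferred(self):
        lib = [entry(1, 0, 100.0)]
        dets = [det(300, 1050)]
        ea = assign_edge_plants({"top_edge": [], "bottom_edge": [0]},
                                dets, {0: 0}, lib, "drift_up", {}, self.cfg,
                                spacing=100.0)
        assert ea.deferred == [0]
        assert ea.minted == [] and ea.matched == {}

    def test_missed_intermediate_does_not_shift_identity(self):
        # the plant adjacent to the anchor is not detected this frame; the
        # entering plant two gaps away must still map to its own ordinal
        lib = [entry(k + 1, k, 100.0 * k,
                     status=OUT_OF_VIEW if k < 10 else IN_VIEW)
               for k in range(20)]
        a = det(300, 450)  # ordinal 10 tracked as middle
        dets = [a, det(300, 250)]  # entering det is two gaps above the anchor
        ea = assign_edge_plants({"top_edge": [1], "bottom_edge": []},
                                dets, {1: 0}, lib, "drift_down",
                                {0: lib[10]}, self.cfg, spacing=100.0)
        assert ea.matched[1].ordinal == 8
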