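"""Identity measures and HOTA, checked against independent oracles.

The oracles deliberately share no code with the implementation: trajectory
matching is done with networkx max-weight matching or exhaustive
enumeration, per-frame matching by permutation search, and box overlap by a
locally defined IOU.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from rowtrack.io import Detection, MOTSequence
from rowtrack.metrics import (DEFAULT_ALPHAS, evaluate, hota,
                              identity_measures, match_frames)
from rowtrack.simulate import FieldSpec, MotionProfile, NoiseSpec, generate_field, simulate_pass


# ----------------------------------------------------------------- oracles

def _iou_ref(a, b):
    ax1, ay1 = a.cx - a.w / 2, a.cy - a.h / 2
    ax2, ay2 = a.cx + a.w / 2, a.cy + a.h / 2
    bx1, by1 = b.cx - b.w / 2, b.cy - b.h / 2
    bx2, by2 = b.cx + b.w / 2, b.cy + b.h / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.w * a.h + b.w * b.h - inter)


def identity_oracle(gt, pred, alpha=0.5):
    """IDTP/IDFP/IDFN via networkx max-weight bipartite matching on
    trajectory co-location counts."""
    weights = {}
    frames = sorted(set(gt.frames) | set(pred.frames))
    for f in frames:
        for g in gt.frames.get(f, []):
            for p in pred.frames.get(f, []):
                if _iou_ref(g, p) >= alpha:
                    weights[(g.id, p.id)] = weights.get((g.id, p.id), 0) + 1
    G = nx.Graph()
    for (g, p), w in weights.items():
        G.add_edge(("g", g), ("p", p), weight=w)
    matching = nx.max_weight_matching(G)
    idtp = 0
    for u, v in matching:
        g, p = (u, v) if u[0] == "g" else (v, u)
        idtp += weights.get((g[1], p[1]), 0)
    n_gt = sum(len(v) for v in gt.frames.values())
    n_pr = sum(len(v) for v in pred.frames.values())
    idfn, idfp = n_gt - idtp, n_pr - idtp
    return {"IDTP": idtp, "IDFN": idfn, "IDFP": idfp,
            "IDF1": 2 * idtp / (2 * idtp + idfp + idfn),
            "IDR": idtp / (idtp + idfn) if idtp + idfn else 1.0,
            "IDP": idtp / (idtp + idfp) if idtp + idfp else 1.0}


def frame_match_oracle(g_boxes, p_boxes, alpha):
    """Best per-frame matching by exhaustive permutation search."""
    best, best_pairs = -1.0, []
    idx = range(len(p_boxes))
    for k in range(min(len(g_boxes), len(p_boxes)), -1, -1):
        for g_sel in itertools.combinations(range(len(g_boxes)), k):
            for p_sel in itertools.permutations(idx, k):
                ious = [_iou_ref(g_boxes[i], p_boxes[j])
                        for i, j in zip(g_sel, p_sel)]
                if any(v < alpha or v <= 0 for v in ious):
                    continue
                score = (k, sum(ious))
                if best_pairs and score <= best:
                    continue
                best, best_pairs = score, list(zip(g_sel, p_sel))
        if best_pairs:
            break
    return best_pairs


def hota_oracle(gt, pred, alphas=DEFAULT_ALPHAS):
    """Direct transcription of the HOTA definitions for tiny sequences."""
    frames = sorted(set(gt.frames) | set(pred.frames))
    n_gt = sum(len(v) for v in gt.frames.values())
    n_pr = sum(len(v) for v in pred.frames.values())
    gt_count, pr_count = {}, {}
    for f in frames:
        for d in gt.frames.get(f, []):
            gt_count[d.id] = gt_count.get(d.id, 0) + 1
        for d in pred.frames.get(f, []):
            pr_count[d.id] = pr_count.get(d.id, 0) + 1
    out = {}
    for a in alphas:
        tps = []
        for f in frames:
            g, p = gt.frames.get(f, []), pred.frames.get(f, [])
            for i, j in frame_match_oracle(g, p, a):
                tps.append((g[i].id, p[j].id))
        tp = len(tps)
        det_a = tp / (tp + (n_gt - tp) + (n_pr - tp)) if n_gt + n_pr else 1.0
        pair = {}
        for key in tps:
            pair[key] = pair.get(key, 0) + 1
        if tp:
            ass_re = sum(pair[k] / gt_count[k[0]] for k in tps) / tp
            ass_pr = sum(pair[k] / pr_count[k[1]] for k in tps) / tp
            ass_a = ass_re * ass_pr / (ass_re + ass_pr - ass_re * ass_pr)
        else:
            ass_re = ass_pr = ass_a = 0.0
        out[a] = {"DetA": det_a, "AssA": ass_a,
                  "HOTA": math.sqrt(det_a * ass_a)}
    return out


# ----------------------------------------------------------------- helpers

def two_track_swap():
    """Two parallel tracks of length 4; predictions swap IDs at frame 3."""
    gt, pred = MOTSequence(), MOTSequence()
    for f in range(1, 5):
        gt.add(Detection(frame=f, id=1, cx=100, cy=100 + 10 * f, w=50, h=50))
        gt.add(Detection(frame=f, id=2, cx=300, cy=100 + 10 * f, w=50, h=50))
        a, b = (1, 2) if f <= 2 else (2, 1)
        pred.add(Detection(frame=f, id=a, cx=100, cy=100 + 10 * f, w=50, h=50))
        pred.add(Detection(frame=f, id=b, cx=300, cy=100 + 10 * f, w=50, h=50))
    return gt, pred


def simulated_pair(seed):
    """A small simulated gt and a degraded, relabeled prediction."""
    rng = np.random.default_rng(seed)
    field = generate_field(FieldSpec(
        plants_per_lane=8, in_lane_spacing_mean=200.0,
        in_lane_spacing_jitter=10.0, box_w_mean=90.0, box_h_mean=90.0,
        box_size_jitter=5.0, seed=seed))
    _, gt = simulate_pass(field, MotionProfile.straight(60, 8.0),
                          NoiseSpec(seed=seed))
    relabel = {i: 100 + int(j) for i, j in
               zip(range(1, 17), rng.permutation(range(1, 17)))}
    pred = MOTSequence()
    spurious = 900
    for f, dets in gt:
        for d in dets:
            if rng.random() < 0.1:
                continue  # dropped box
            pid = relabel[d.id]
            if rng.random() < 0.05:
                spurious += 1  # spurious identity
                pid = spurious
            pred.add(Detection(frame=f, id=pid, cx=d.cx + rng.normal(0, 1),
                               cy=d.cy + rng.normal(0, 1), w=d.w, h=d.h))
    return gt, pred


# ------------------------------------------------------------------- tests

class TestMatchFrames:
    def test_identical_sequences_all_tp(self):
        gt, _ = two_track_swap()
        for alpha in (0.05, 0.5, 0.9):
            matches = match_frames(gt, gt, alpha)
            assert all(len(m) == 2 for m in matches.values())

    def test_empty_prediction_all_fn(self):
        gt, _ = two_track_swap()
        matches = match_frames(gt, MOTSequence(), 0.5)
        assert all(m == [] for m in matches.values())

    def test_matching_equals_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = [Detection(frame=1, id=k + 1, cx=rng.uniform(0, 300),
                           cy=rng.uniform(0, 300), w=60, h=60)
                 for k in range(3)]
            p = [Detection(frame=1, id=k + 1, cx=rng.uniform(0, 300),
                           cy=rng.uniform(0, 300), w=60, h=60)
                 for k in range(3)]
            gt, pred = MOTSequence(), MOTSequence()
            for d in g:
                gt.add(d)
            for d in p:
                pred.add(d)
            got = match_frames(gt, pred, 0.3)[1]
            want = frame_match_oracle(g, p, 0.3)
            assert len(got) == len(want)
            got_iou = sum(_iou_ref(a, b) for a, b in got)
            want_iou = sum(_iou_ref(g[i], p[j]) for i, j in want)
            assert got_iou == pytest.approx(want_iou, abs=1e-12)


class TestIdentityMeasures:
    def test_perfect_prediction(self):
        gt, _ = two_track_swap()
        m = identity_measures(gt, gt)
        assert (m["IDF1"], m["IDR"], m["IDP"], m["IDSW"]) == (1, 1, 1, 0)

    def test_two_track_swap_toy(self):
        gt, pred = two_track_swap()
        m = identity_measures(gt, pred)
        assert m["IDTP"] == 4 and m["IDFP"] == 4 and m["IDFN"] == 4
        assert m["IDF1"] == pytest.approx(0.5)
        assert m["IDSW"] == 2

    def test_relabeled_prediction_is_perfect(self):
        gt, _ = two_track_swap()
        pred = MOTSequence()
        for f, dets in gt:
            for d in dets:
                pred.add(Detection(frame=f, id=d.id + 40, cx=d.cx, cy=d.cy,
                                   w=d.w, h=d.h))
        m = identity_measures(gt, pred)
        assert m["IDF1"] == 1.0 and m["IDSW"] == 0

    def test_agrees_with_independent_matching_oracle(self):
        for seed in range(10):
            gt, pred = simulated_pair(seed)
            mine = identity_measures(gt, pred)
            ref = identity_oracle(gt, pred)
            for key in ("IDTP", "IDFP", "IDFN", "IDF1", "IDR", "IDP"):
                assert mine[key] == pytest.approx(ref[key], abs=1e-9), (seed, key)


class TestHota:
    def test_perfect_prediction(self):
        gt, _ = two_track_swap()
        h = hota(gt, gt)
        for key in ("HOTA", "DetA", "AssA", "AssRe", "AssPr"):
            assert h[key] == pytest.approx(1.0)

    def test_eq_identities_hold_per_alpha(self):
        gt, pred = two_track_swap()
        h = hota(gt, pred)
        for a, v in h["per_alpha"].items():
            assert v["HOTA"] ** 2 == pytest.approx(v["DetA"] * v["AssA"],
                                                   abs=1e-12)
            lhs = v["AssA"] * (v["AssRe"] + v["AssPr"]
                               - v["AssRe"] * v["AssPr"])
            assert lhs == pytest.approx(v["AssRe"] * v["AssPr"], abs=1e-12)

    def test_deleted_trajectory_matches_reference_definition(self):
        gt, _ = two_track_swap()
        pred = MOTSequence()
        for f, dets in gt:
            for d in dets:
                if d.id == 2:
                    continue
                pred.add(Detection(frame=f, id=d.id, cx=d.cx, cy=d.cy,
                                   w=d.w, h=d.h))
        mine = hota(gt, pred)
        ref = hota_oracle(gt, pred)
        for a in DEFAULT_ALPHAS:
            for key in ("DetA", "AssA", "HOTA"):
                assert mine["per_alpha"][float(a)][key] == pytest.approx(
                    ref[a][key], abs=1e-12)
        assert mine["DetA"] < 1.0

    def test_swap_toy_matches_reference_definition(self):
        gt, pred = two_track_swap()
        mine = hota(gt, pred)
        ref = hota_oracle(gt, pred)
        for a in DEFAULT_ALPHAS:
            assert mine["per_alpha"][float(a)]["HOTA"] == pytest.approx(
                ref[a]["HOTA"], abs=1e-12)


def test_evaluate_bundles_all_fields():
    gt, pred = two_track_swap()
    rep = evaluate(gt, pred)
    d = rep.as_dict()
    for key in ("IDSW", "IDF1", "IDR", "IDP", "HOTA", "DetA", "AssA",
                "AssRe", "AssPr"):
        assert key in d
    for key in ("IDF1", "IDR", "IDP", "HOTA", "DetA", "AssA", "AssRe", "AssPr"):
        assert 0.0 <= d[key] <= 1.0
    assert rep.IDF1 == pytest.approx(
        2 * rep.IDTP / (2 * rep.IDTP + rep.IDFP + rep.IDFN))
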