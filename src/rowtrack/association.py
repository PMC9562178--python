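"""Data association: fused cost matrix, library window, edge-plant ID logic.

The matcher fuses two complementary cues into one cost matrix:

* the Euclidean distance between neighbor-geometry features (valid even for
  plants that left the view long ago), and
* the IOU between each detection and the Kalman-predicted box of each
  candidate (strong for plants continuously in view),

combined as ``final = feat - iou`` so that a small feature distance and a
large overlap both pull the cost down.  Candidates are not the whole object
library but a window of entries spatially adjacent to the most advanced
plant seen in the previous frame; with several lanes interleaving IDs the
window is indexed by per-lane planting *ordinals* rather than raw IDs (raw
IDs remain available for single-lane data).

Plants at the top/bottom image edge have no complete neighbor pair and no
feature; they are resolved from the estimated travel direction: the leaving
side is matched to Kalman predictions by IOU, the entering side either
receives fresh IDs (when the nearest tracked middle plant is the most
advanced plant ever seen in its lane) or is re-identified as the library
entries adjacent to that plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Detection
from .features import PlantFeature, feature_distance
from .motion import KalmanTrackState, iou

__all__ = [
    "LibraryEntry",
    "CostMatrices",
    "AssociationConfig",
    "build_cost_matrices",
    "hungarian_match",
    "candidate_window",
    "estimate_direction",
    "assign_edge_plants",
    "EdgeAssignment",
]

IN_VIEW = "in_view"
OUT_OF_VIEW = "out_of_view"


@dataclass
class LibraryEntry:
    """A tracked plant's identity record in the object library."""

    plant_id: int
    lane: int
    ordinal: int  # position in the lane's planting order; may go negative
    feature: Optional[PlantFeature]
    last_box: Detection
    kstate: KalmanTrackState
    last_seen_frame: int
    status: str = IN_VIEW

    def predicted_box(self) -> Optional[tuple]:
        """Kalman-predicted box, or ``None`` once the plant is out of view
        (stale predictions are frozen and contribute zero IOU)."""
        if self.status == OUT_OF_VIEW:
            return None
        return self.kstate.box


@dataclass(frozen=True)
class AssociationConfig:
    """Tunables of the association stage.

    ``x1``/``x2``: candidate-window radii below/above the anchor ordinal.
    ``tau_feat``: neutral feature cost used for candidates without a stored
    feature, and a gate on pure feature distance.
    ``tau_final``: acceptance threshold on the fused cost — assigned pairs
    costing more are demoted to unmatched and the detection treated as new.
    ``eps_dir``: dead-band in pixels for travel-direction estimation.
    ``window_mode``: ``"ordinal"`` (per-lane planting order, default) or
    ``"raw_id"`` (the single-lane convention of windowing on ID numbers).
    ``feature_ema``: exponential-averaging weight for stored features
    (0 = replace with the latest extraction, the default).
    """

    x1: int = 3
    x2: int = 3
    tau_feat: float = 0.5
    tau_final: float = 0.5
    eps_dir: float = 2.0
    window_mode: str = "ordinal"
    feature_ema: float = 0.0

    def __post_init__(self):
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("window radii x1, x2 must be >= 0")
        if self.window_mode not in ("ordinal", "raw_id"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if not (0.0 <= self.feature_ema < 1.0):
            raise ValueError("feature_ema must lie in [0, 1)")


@dataclass
class CostMatrices:
    """The three |detections| x |candidates| matrices of the fused matcher."""

    feat: np.ndarray
    iou: np.ndarray
    final: np.ndarray = field(init=False)

    def __post_init__(self):
        self.final = self.feat - self.iou


def build_cost_matrices(
    dets_with_features: Sequence[Tuple[Detection, Optional[PlantFeature]]],
    candidates: Sequence[LibraryEntry],
    tau_feat: float = 0.5,
) -> CostMatrices:
    """Feature, IOU and fused cost matrices between detections and library
    candidates.

    A candidate without a stored feature (seen only at the image edge so
    far) takes the neutral feature cost ``tau_feat`` and competes on IOU
    alone; an out-of-view candidate contributes zero IOU and competes on
    feature alone.
    """
    n, m = len(dets_with_features), len(candidates)
    feat = np.zeros((n, m))
    iou_m = np.zeros((n, m))
    for j, cand in enumerate(candidates):
        pbox = cand.predicted_box()
        for i, (det, f) in enumerate(dets_with_features):
            if f is not None and cand.feature is not None:
                feat[i, j] = feature_distance(f, cand.feature)
            else:
                feat[i, j] = tau_feat
            if pbox is not None:
                iou_m[i, j] = iou(det.box, pbox)
    return CostMatrices(feat=feat, iou=iou_m)


def hungarian_match(final: np.ndarray, tau_final: float = math.inf
                    ) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Minimum-cost one-to-one assignment with cost gating.

    Returns ``(assignments, unmatched_rows, unmatched_cols)``.  Assigned
    pairs whose cost exceeds ``tau_final`` are demoted to unmatched — a
    detection whose best library match is still too costly is treated as a
    new plant.  Assignments are sorted by row index (deterministic).
    """
    final = np.asarray(final, dtype=float)
    if final.ndim != 2:
        raise ValueError("cost matrix must be 2-D")
    n, m = final.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    if not np.all(np.isfinite(final)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(final)
    assignments, unmatched_rows, unmatched_cols = [], [], []
    assigned_r, assigned_c = set(), set()
    for r, c in sorted(zip(rows, cols)):
        if final[r, c] > tau_final:
            continue
        assignments.append((int(r), int(c)))
        assigned_r.add(int(r))
        assigned_c.add(int(c))
    unmatched_rows = [i for i in range(n) if i not in assigned_r]
    unmatched_cols = [j for j in range(m) if j not in assigned_c]
    return assignments, unmatched_rows, unmatched_cols


def candidate_window(library: Sequence[LibraryEntry], anchor: LibraryEntry,
                     x1: int, x2: int, mode: str = "ordinal") -> List[LibraryEntry]:
    """Library entries within the adjacency window around an anchor plant.

    In ``ordinal`` mode: same-lane entries whose planting ordinal lies in
    ``[anchor.ordinal - x1, anchor.ordinal + x2]``, ascending.  In
    ``raw_id`` mode the window is taken on ID numbers instead (sensible
    only for single-lane data where IDs follow planting order).
    Entries beyond the lane's known extent simply do not exist yet.
    """
    if mode == "raw_id":
        lo, hi = anchor.plant_id - x1, anchor.plant_id + x2
        sel = [e for e in library if lo <= e.plant_id <= hi]
        sel.sort(key=lambda e: e.plant_id)
    else:
        lo, hi = anchor.ordinal - x1, anchor.ordinal + x2
        sel = [e for e in library if e.lane == anchor.lane and lo <= e.ordinal <= hi]
        sel.sort(key=lambda e: e.ordinal)
    return sel


def estimate_direction(matched_pairs: Sequence[Tuple[Detection, Detection]],
                       eps_dir: float = 2.0) -> str:
    """Estimate apparent plant drift from matched (previous, current) pairs.

    Median of ``curr.cy - prev.cy``; returns ``"drift_down"``, ``"drift_up"``
    or ``"stationary"`` (also for an empty list).  The median makes the
    estimate robust to individual mismatches.
    """
    if not matched_pairs:
        return "stationary"
    deltas = sorted(c.cy - p.cy for p, c in matched_pairs)
    n = len(deltas)
    med = deltas[n // 2] if n % 2 else 0.5 * (deltas[n // 2 - 1] + deltas[n // 2])
    if med > eps_dir:
        return "drift_down"
    if med < -eps_dir:
        return "drift_up"
    return "stationary"


@dataclass
class EdgeAssignment:
    """Outcome of edge-plant ID resolution for one frame.

    ``matched``: det index -> existing library entry.
    ``minted``: det index -> (lane, ordinal) for fresh entries, in minting
    order.  ``deferred``: det indices left unassigned this frame.
    """

    matched: Dict[int, LibraryEntry] = field(default_factory=dict)
    minted: List[Tuple[int, int, int]] = field(default_factory=list)  # (det_idx, lane, ordinal)
    deferred: List[int] = field(default_factory=list)


def _iou_match_side(det_indices: List[int], dets: Sequence[Detection],
                    entries: List[LibraryEntry], min_iou: float,
                    out: EdgeAssignment) -> None:
    """Match edge detections on the leaving side to Kalman predictions by
    maximum IOU (Hungarian on negated IOU)."""
    usable = [e for e in entries if e.predicted_box() is not None]
    if not det_indices:
        return
    if not usable:
        out.deferred.extend(det_indices)
        return
    cost = np.zeros((len(det_indices), len(usable)))
    for r, i in enumerate(det_indices):
        for c, e in enumerate(usable):
            cost[r, c] = -iou(dets[i].box, e.predicted_box())
    assignments, un_r, _ = hungarian_match(cost, tau_final=-min_iou)
    for r, c in assignments:
        out.matched[det_indices[r]] = usable[c]
    out.deferred.extend(det_indices[r] for r in un_r)


def assign_edge_plants(
    edge_partition: Dict[str, List[int]],
    dets: Sequence[Detection],
    lane_of: Dict[int, int],
    library: Sequence[LibraryEntry],
    direction: str,
    tracked_middle: Dict[int, LibraryEntry],
    cfg: AssociationConfig,
    min_iou: float = 0.05,
    spacing: Optional[float] = None,
) -> EdgeAssignment:
    """Resolve IDs of top/bottom edge detections from the travel direction.

    The *leaving* side (the side plants drift toward: top under
    ``drift_up``, bottom under ``drift_down``) is matched to previous-frame
    Kalman predictions by IOU.  On the *entering* side, let ``A`` be the
    nearest successfully tracked middle plant in the same lane: each edge
    detection's planting ordinal is inferred from its pixel distance to
    ``A`` (gap count rounded against the in-lane ``spacing``, so a missed
    detection between them cannot shift the count); an existing library
    entry at that ordinal re-identifies the plant, an ordinal beyond the
    lane's known extent mints a fresh ID.  Under ``stationary`` both sides
    are IOU-matched and nothing is minted.  Entering-side detections with
    no tracked middle anchor in their lane are deferred, as are ordinal
    conflicts.
    """
    out = EdgeAssignment()
    top = list(edge_partition.get("top_edge", []))
    bottom = list(edge_partition.get("bottom_edge", []))
    claimed = {e.plant_id for e in tracked_middle.values()}
    free = [e for e in library if e.plant_id not in claimed]

    if direction == "stationary":
        _iou_match_side(top + bottom, dets, free, min_iou, out)
        return out

    if direction == "drift_up":
        leaving, entering, step = top, bottom, +1
    else:  # drift_down
        leaving, entering, step = bottom, top, -1

    _iou_match_side(leaving, dets, free, min_iou, out)
    claimed |= {e.plant_id for e in out.matched.values()}

    # Entering side: a plant already minted on a previous frame keeps its ID
    # through plain IOU continuity (its clipped box grows as it enters, so
    # its center shifts and must not re-enter ordinal inference); only
    # detections with no overlapping prediction are resolved by ordinals.
    free = [e for e in free if e.plant_id not in claimed]
    first_seen = list(entering)
    _iou_match_side(first_seen, dets, free, min_iou, out)
    entering = [i for i in out.deferred if i in first_seen]
    out.deferred = [i for i in out.deferred if i not in first_seen]
    claimed |= {e.plant_id for e in out.matched.values()}

    by_lane: Dict[int, List[int]] = {}
    for i in entering:
        by_lane.setdefault(lane_of[i], []).append(i)
    for lane, det_idx in sorted(by_lane.items()):
        # entry order: nearest to the image middle first
        det_idx.sort(key=lambda i: dets[i].cy, reverse=(step < 0))
        anchors = [(i, e) for i, e in tracked_middle.items()
                   if e.lane == lane]
        if not anchors:
            out.deferred.extend(det_idx)
            continue
        # A = tracked middle plant nearest the entering side
        a_idx, A = max(anchors, key=lambda t: step * t[1].ordinal)
        lane_entries = {e.ordinal: e for e in library if e.lane == lane}
        extreme = max(lane_entries) if step > 0 else min(lane_entries)
        used_ords = set()
        for i in det_idx:
            if spacing is not None and spacing > 0:
                # measure the gap on the box side away from the image
                # border: an entering box is clipped at the border, which
                # shifts its center but not its inner edge
                if step < 0:  # entering at the top; bottoms are unclipped
                    delta = ((dets[a_idx].cy + dets[a_idx].h / 2)
                             - (dets[i].cy + dets[i].h / 2))
                else:  # entering at the bottom; tops are unclipped
                    delta = ((dets[i].cy - dets[i].h / 2)
                             - (dets[a_idx].cy - dets[a_idx].h / 2))
                gaps = max(1, round(delta / spacing))
            else:
                gaps = len(used_ords) + 1
            ord_est = A.ordinal + step * gaps
            if ord_est in used_ords:
                ord_est += step
            entry = lane_entries.get(ord_est)
            if entry is not None and entry.plant_id not in claimed:
                out.matched[i] = entry
                claimed.add(entry.plant_id)
                used_ords.add(ord_est)
            elif entry is None and (
                    (step > 0 and ord_est > extreme)
                    or (step < 0 and ord_est < extreme)):
                out.minted.append((i, lane, ord_est))
                used_ords.add(ord_est)
            else:
                out.deferred.append(i)
    return out
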