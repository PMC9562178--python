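"""Per-frame tracking pipeline and object-library maintenance.

Each frame runs: center-line fit -> lane split -> middle/edge partition ->
neighbor-feature extraction -> fused-cost Hungarian association of middle
plants against a library window -> travel-direction estimate ->
direction-aware edge-plant ID resolution -> Kalman/library update.  The
object library never forgets a plant, which is what allows a plant that
left the field of view (robot reversing, long dropout) to recover its
original ID when it re-appears.

A SORT-style ablation (``iou_only=True``) replaces all of the above with
plain IOU association against currently in-view tracks — no features, no
library window, no edge logic — and is the baseline against which the
re-identification mechanism is demonstrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import Detection, MOTSequence
from .geometry import (DegenerateGeometryError, classify_middle_plants,
                       fit_center_line, split_lanes)
from .features import (FeatureWeights, PlantFeature, extract_feature,
                       feature_distance, median_neighbor_spacing,
                       spacing_weights)
from .motion import KalmanParams, kf_initiate, kf_predict, kf_update, iou
from .association import (IN_VIEW, OUT_OF_VIEW, AssociationConfig,
                          LibraryEntry, assign_edge_plants,
                          build_cost_matrices, candidate_window,
                          estimate_direction, hungarian_match)

__all__ = ["TrackerConfig", "TrackerState", "PlantTracker", "run_sequence"]


@dataclass(frozen=True)
class TrackerConfig:
    """All tunables of the tracking pipeline in one place.

    ``weights=None`` selects per-frame spacing-normalized feature weights
    (``c1 = c2 = 1/median in-lane spacing``, ``cw = ch = 1``).
    ``patience`` is the number of frames a track survives unseen before it
    is declared out of view and its prediction frozen.
    """

    n_lanes: int = 2
    min_conf: float = 0.3
    weights: Optional[FeatureWeights] = None
    association: AssociationConfig = field(default_factory=AssociationConfig)
    kalman: KalmanParams = field(default_factory=KalmanParams)
    patience: int = 3
    iou_only: bool = False
    iou_only_min_iou: float = 0.1
    edge_min_iou: float = 0.05


@dataclass
class TrackerState:
    """Mutable cross-frame state: the object library and bookkeeping."""

    library: List[LibraryEntry] = field(default_factory=list)
    next_id: int = 1
    frame_index: int = 0  # last processed frame, 0 before the first
    prev_boxes: Dict[int, Detection] = field(default_factory=dict)

    def entry_by_id(self, plant_id: int) -> Optional[LibraryEntry]:
        for e in self.library:
            if e.plant_id == plant_id:
                return e
        return None


class PlantTracker:
    """Stateful tracker; feed frames in order via :meth:`process_frame`.

    A detector plug-in is not required — any callable producing
    per-frame :class:`~rowtrack.io.Detection` lists can feed this class —
    but the usual entry point is :func:`run_sequence` on a detection file.
    """

    def __init__(self, config: TrackerConfig = TrackerConfig(),
                 image_height: Optional[float] = None):
        self.config = config
        self.state = TrackerState()
        # image height lets the tracker recognize boxes clipped at the
        # bottom border (the top border is always y = 0)
        self.image_height = image_height

    # ------------------------------------------------------------------ #

    def process_frame(self, dets: List[Detection],
                      frame: Optional[int] = None) -> List[Detection]:
        """Associate one frame of detections; returns detections with IDs.

        Detections below the confidence floor are dropped; detections that
        cannot be resolved this frame (no geometric anchor) are deferred and
        omitted from the output.  Output is sorted by ID.
        """
        cfg = self.config
        st = self.state
        if frame is None:
            if not dets:
                raise ValueError("cannot infer frame index from an empty list")
            frame = dets[0].frame
        if any(d.frame != frame for d in dets):
            raise ValueError("all detections must come from the same frame")
        if frame <= st.frame_index:
            raise ValueError(
                f"frame indices must be strictly increasing "
                f"({frame} after {st.frame_index})")
        dt = frame - st.frame_index if st.frame_index else 1
        for e in st.library:
            if e.status == IN_VIEW:
                kf_predict(e.kstate, cfg.kalman, dt=dt)
        dets = [d for d in dets if d.conf >= cfg.min_conf]

        if cfg.iou_only:
            emitted = self._associate_iou_only(dets, frame)
        else:
            emitted = self._associate(dets, frame)

        for e in st.library:
            if e.status == IN_VIEW and frame - e.last_seen_frame > cfg.patience:
                e.status = OUT_OF_VIEW
        st.frame_index = frame
        st.prev_boxes = {d.id: d for d in emitted}
        return sorted(emitted, key=lambda d: d.id)

    # ------------------------------------------------------------------ #

    def _mint(self, det: Detection, lane: int, ordinal: int, frame: int,
              feat: Optional[PlantFeature] = None) -> LibraryEntry:
        st = self.state
        entry = LibraryEntry(
            plant_id=st.next_id, lane=lane, ordinal=ordinal, feature=feat,
            last_box=det, kstate=kf_initiate(det, self.config.kalman),
            last_seen_frame=frame, status=IN_VIEW)
        st.next_id += 1
        st.library.append(entry)
        return entry

    def _observe(self, entry: LibraryEntry, det: Detection, frame: int,
                 feat: Optional[PlantFeature] = None) -> None:
        """Record a confirmed observation of a library entry."""
        cfg = self.config
        if entry.status == OUT_OF_VIEW:
            # re-entry after an out-of-view gap: restart the motion model
            entry.kstate = kf_initiate(det, cfg.kalman)
        else:
            kf_update(entry.kstate, det, cfg.kalman)
        entry.last_box = det
        entry.last_seen_frame = frame
        entry.status = IN_VIEW
        if feat is not None:
            a = cfg.association.feature_ema
            if a > 0 and entry.feature is not None:
                old, new = entry.feature, feat
                entry.feature = PlantFeature(
                    d1=a * old.d1 + (1 - a) * new.d1,
                    d2=a * old.d2 + (1 - a) * new.d2,
                    wr=a * old.wr + (1 - a) * new.wr,
                    hr=a * old.hr + (1 - a) * new.hr)
            else:
                entry.feature = feat

    def _anchor(self, lane_entries: List[LibraryEntry]) -> LibraryEntry:
        """The same-lane entry of largest ordinal among those seen most
        recently — the window center of the candidate search."""
        latest = max(e.last_seen_frame for e in lane_entries)
        return max((e for e in lane_entries if e.last_seen_frame == latest),
                   key=lambda e: e.ordinal)

    # ------------------------------------------------------------------ #

    def _associate(self, dets: List[Detection], frame: int) -> List[Detection]:
        cfg, st = self.config, self.state
        if not dets:
            return []
        try:
            line = fit_center_line([(d.cx, d.cy) for d in dets])
            la = split_lanes(dets, line, cfg.n_lanes)
        except DegenerateGeometryError:
            return self._fallback_iou(dets, frame)
        parts = classify_middle_plants(la)

        spacing = median_neighbor_spacing(la)
        weights = cfg.weights
        if weights is None:
            weights = spacing_weights(spacing) if spacing == spacing else FeatureWeights()

        # A neighbor gap well beyond the in-lane spacing means the true
        # neighbor was not detected this frame: the feature would encode the
        # wrong plant pair, so the detection is treated as featureless and
        # competes on IOU alone (and no corrupted feature enters the
        # library).  A feature computed while any of the three boxes is
        # clipped at the image border is still usable for matching, but is
        # not stored: the clipped center is shifted, and the stored feature
        # must describe the plant, not the viewport.
        feats: Dict[int, PlantFeature] = {}
        feats_store: Dict[int, PlantFeature] = {}
        max_gap = 1.5 * spacing if spacing == spacing else float("inf")
        margin = 2.0
        for lane, order in la.order_in_lane.items():
            for pos in range(1, len(order) - 1):
                up, mid, dn = (dets[order[pos - 1]], dets[order[pos]],
                               dets[order[pos + 1]])
                if (mid.cy - up.cy) > max_gap or (dn.cy - mid.cy) > max_gap:
                    continue
                f = extract_feature(mid, up, dn, weights)
                feats[order[pos]] = f
                clipped = up.cy - up.h / 2 <= margin
                if self.image_height is not None:
                    clipped = clipped or (
                        dn.cy + dn.h / 2 >= self.image_height - margin)
                if not clipped:
                    feats_store[order[pos]] = f

        emitted: Dict[int, Detection] = {}   # det index -> det with id
        tracked_middle: Dict[int, LibraryEntry] = {}
        cold_lanes = set()

        # -- cold start: lanes with no library entries mint everything -----
        for lane in sorted(la.order_in_lane):
            order = la.order_in_lane[lane]
            if not order:
                continue
            if not any(e.lane == lane for e in st.library):
                cold_lanes.add(lane)
                # ordinal increments follow the rounded gap count so that a
                # plant missed by the detector this frame keeps a reserved
                # slot in the lane's planting order
                ordinal = 0
                prev_cy = None
                for i in order:
                    if prev_cy is not None:
                        if spacing == spacing and spacing > 0:
                            ordinal += max(1, round((dets[i].cy - prev_cy)
                                                    / spacing))
                        else:
                            ordinal += 1
                    prev_cy = dets[i].cy
                    entry = self._mint(dets[i], lane, ordinal, frame,
                                       feats_store.get(i))
                    emitted[i] = dets[i].with_id(entry.plant_id)
                    if i in feats:
                        tracked_middle[i] = entry

        # -- middle-plant association against the library window ----------
        assoc = cfg.association
        for lane in sorted(la.order_in_lane):
            if lane in cold_lanes:
                continue
            order = la.order_in_lane[lane]
            lane_middle = [i for i in order[1:-1]]
            if not lane_middle:
                continue
            lane_entries = [e for e in st.library if e.lane == lane]
            anchor = self._anchor(lane_entries)
            cands = candidate_window(st.library, anchor, assoc.x1, assoc.x2,
                                     assoc.window_mode)
            mats = build_cost_matrices(
                [(dets[i], feats.get(i)) for i in lane_middle], cands,
                assoc.tau_feat)
            # Admissibility gate: a pair must either overlap the candidate's
            # prediction (in-view continuity) or be a genuine
            # re-identification — an out-of-view plant, within the feature
            # gate, whose planting ordinal agrees with the detection's own
            # ordinal as read off the in-view predictions.  This keeps a
            # chance feature coincidence elsewhere in the lane from
            # stealing a detection away from its motion-confirmed track.
            chart = [(e.ordinal, e.predicted_box()[1]) for e in lane_entries
                     if e.predicted_box() is not None]
            ord_est: List[Optional[int]] = []
            for i in lane_middle:
                if chart and spacing == spacing:
                    o, py = min(chart, key=lambda t: abs(t[1] - dets[i].cy))
                    ord_est.append(o + round((dets[i].cy - py) / spacing))
                else:
                    ord_est.append(None)
            final = mats.final.copy()
            for c, cand in enumerate(cands):
                for r in range(len(lane_middle)):
                    ok = mats.iou[r, c] >= cfg.edge_min_iou or (
                        cand.status == OUT_OF_VIEW
                        and mats.feat[r, c] <= assoc.tau_feat
                        and (ord_est[r] is None
                             or abs(cand.ordinal - ord_est[r]) <= 1))
                    if not ok:
                        final[r, c] = 1e6
            pairs, un_rows, _ = hungarian_match(final, assoc.tau_final)
            for r, c in pairs:
                i = lane_middle[r]
                tracked_middle[i] = cands[c]
            # second chance: place unmatched middles by in-lane adjacency
            self._place_unmatched_middles(
                [lane_middle[r] for r in un_rows], lane, dets,
                tracked_middle, frame, spacing)

        for i, entry in tracked_middle.items():
            if i not in emitted:
                self._observe(entry, dets[i], frame, feats_store.get(i))
                emitted[i] = dets[i].with_id(entry.plant_id)

        # -- travel direction from plants tracked in consecutive frames ---
        pairs = [(st.prev_boxes[e.plant_id], dets[i])
                 for i, e in tracked_middle.items()
                 if e.plant_id in st.prev_boxes]
        direction = estimate_direction(pairs, assoc.eps_dir)

        # -- edge plants ---------------------------------------------------
        edge_parts = {
            side: [i for i in parts[side]
                   if la.lane_of[i] not in cold_lanes and i not in emitted]
            for side in ("top_edge", "bottom_edge")}
        ea = assign_edge_plants(edge_parts, dets, la.lane_of, st.library,
                                direction, tracked_middle, assoc,
                                min_iou=cfg.edge_min_iou,
                                spacing=spacing if spacing == spacing else None)
        for i, entry in ea.matched.items():
            self._observe(entry, dets[i], frame)
            emitted[i] = dets[i].with_id(entry.plant_id)
        for i, lane, ordinal in ea.minted:
            entry = self._mint(dets[i], lane, ordinal, frame)
            emitted[i] = dets[i].with_id(entry.plant_id)
        return list(emitted.values())

    def _place_unmatched_middles(self, unmatched: List[int], lane: int,
                                 dets: List[Detection],
                                 tracked_middle: Dict[int, LibraryEntry],
                                 frame: int, spacing: float) -> None:
        """Resolve middle detections the cost matcher left over by in-lane
        position: the detection's planting ordinal is inferred from its
        pixel distance to the nearest tracked plant in the lane (gap count
        rounded against the in-lane spacing).  An existing unclaimed entry
        at that ordinal is re-identified.  A detection bracketed by tracked
        plants whose ordinal interval leaves a genuinely empty slot — a
        plant the detector missed when the lane was first seen — is minted
        into that slot (renumbering the lane if the slot does not exist
        yet).  Anything else (e.g. a false positive sitting between two
        adjacent tracked plants one gap apart) is deferred."""
        st = self.state
        if spacing != spacing or spacing <= 0:  # no usable spacing estimate
            return
        for i in sorted(unmatched, key=lambda j: dets[j].cy):
            in_lane = [(j, e) for j, e in tracked_middle.items()
                       if e.lane == lane]
            if not in_lane:
                continue
            j, near = min(in_lane,
                          key=lambda t: abs(dets[t[0]].cy - dets[i].cy))
            delta = dets[i].cy - dets[j].cy
            gaps = round(abs(delta) / spacing)
            if gaps == 0:
                continue  # overlaps a tracked plant: duplicate or FP
            slot = near.ordinal + (gaps if delta > 0 else -gaps)
            lane_entries = {e.ordinal: e for e in st.library if e.lane == lane}
            claimed = {e.plant_id for e in tracked_middle.values()}
            entry = lane_entries.get(slot)
            if entry is not None and entry.plant_id not in claimed:
                tracked_middle[i] = entry
                continue
            # bracketing tracked plants around the detection
            above = [(dets[k].cy, e) for k, e in in_lane
                     if dets[k].cy < dets[i].cy]
            below = [(dets[k].cy, e) for k, e in in_lane
                     if dets[k].cy > dets[i].cy]
            if not (above and below):
                continue
            a_cy, a_e = max(above)
            b_cy, b_e = min(below)
            span = round((b_cy - a_cy) / spacing)
            if span < 2 or b_e.ordinal <= a_e.ordinal:
                continue
            hole = a_e.ordinal + round((dets[i].cy - a_cy) / spacing)
            if hole <= a_e.ordinal or hole >= a_e.ordinal + span:
                continue
            if b_e.ordinal - a_e.ordinal < span:
                # lane numbering has no room: a plant was missed when the
                # lane was first enumerated; renumber everything below
                for e in st.library:
                    if e.lane == lane and e.ordinal >= hole:
                        e.ordinal += 1
            elif hole in lane_entries:
                continue  # slot exists but its entry is claimed elsewhere
            tracked_middle[i] = self._mint(dets[i], lane, hole, frame)

    # ------------------------------------------------------------------ #

    def _fallback_iou(self, dets: List[Detection], frame: int) -> List[Detection]:
        """Frames too sparse for geometry: IOU-only match, no minting."""
        cfg, st = self.config, self.state
        cands = [e for e in st.library if e.predicted_box() is not None]
        if not dets or not cands:
            return []
        cost = np.zeros((len(dets), len(cands)))
        for r, d in enumerate(dets):
            for c, e in enumerate(cands):
                cost[r, c] = -iou(d.box, e.predicted_box())
        pairs, _, _ = hungarian_match(cost, tau_final=-cfg.edge_min_iou)
        emitted = []
        for r, c in pairs:
            self._observe(cands[c], dets[r], frame)
            emitted.append(dets[r].with_id(cands[c].plant_id))
        return emitted

    def _associate_iou_only(self, dets: List[Detection],
                            frame: int) -> List[Detection]:
        """SORT-style baseline: IOU association against in-view tracks only,
        fresh ID for everything else.  No re-identification is possible."""
        cfg, st = self.config, self.state
        cands = [e for e in st.library if e.status == IN_VIEW]
        emitted = []
        pairs, un_rows = [], list(range(len(dets)))
        if dets and cands:
            cost = np.zeros((len(dets), len(cands)))
            for r, d in enumerate(dets):
                for c, e in enumerate(cands):
                    cost[r, c] = -iou(d.box, e.kstate.box)
            pairs, un_rows, _ = hungarian_match(
                cost, tau_final=-cfg.iou_only_min_iou)
        for r, c in pairs:
            self._observe(cands[c], dets[r], frame)
            emitted.append(dets[r].with_id(cands[c].plant_id))
        for r in un_rows:
            entry = self._mint(dets[r], 0, st.next_id, frame)
            emitted.append(dets[r].with_id(entry.plant_id))
        return emitted


def run_sequence(seq: MOTSequence,
                 config: TrackerConfig = TrackerConfig()) -> MOTSequence:
    """Track a whole detection sequence; deterministic given (seq, config).

    Returns a new :class:`MOTSequence` whose detections carry plant IDs
    (deferred detections omitted).
    """
    tracker = PlantTracker(config, image_height=seq.image_height)
    out = MOTSequence(image_width=seq.image_width,
                      image_height=seq.image_height,
                      name=f"{seq.name}:tracked")
    for f in seq.frame_indices():
        for d in tracker.process_frame(list(seq.frames[f]), frame=f):
            out.add(d)
    return out
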