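"""Synthetic field, camera pass, and detection-noise generator.

Emulates the acquisition geometry of a nadir camera on a row-following
robot: a planar field of plants in parallel lanes with fixed ground
positions, and a camera window that translates along the lane direction
with forward/stop/reverse velocity segments.  Default pixel scales follow
the reference geometry the tracker targets — an 810 x 1080 px cropped
image from a camera 1.5 m above ground at 30 Hz, in-lane plant spacing of
0.3-0.35 m mapping to about 300 px, lane separation about 270 px, and a
robot speed of 0.35-0.45 m/s mapping to about 6 px/frame.  No camera
intrinsics are modeled; the metric-to-pixel mapping is a configuration
choice, so every quantity is exposed.

Ground truth contains every plant whose box is sufficiently visible in the
window, clipped to the window, under a persistent plant ID.  Detections are
the ground-truth boxes perturbed by center/size jitter, thinned by missed
detections, and augmented with uniform false positives (weed/soil
misdetections).  Field randomness and detection noise carry separate seeds
so one field can be replayed under many noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import Detection, MOTSequence

__all__ = ["FieldSpec", "MotionProfile", "NoiseSpec", "GroundPlant",
           "generate_field", "simulate_pass"]


@dataclass(frozen=True)
class FieldSpec:
    """Layout of the planted field, in pixels of the image plane."""

    n_lanes: int = 2
    plants_per_lane: int = 20
    lane_x_positions: Optional[Tuple[float, ...]] = None  # default: evenly spread
    in_lane_spacing_mean: float = 300.0
    in_lane_spacing_jitter: float = 10.0  # uniform +- jitter per gap
    box_w_mean: float = 100.0
    box_h_mean: float = 100.0
    box_size_jitter: float = 8.0  # uniform +- jitter per plant
    first_plant_y: float = 150.0
    seed: int = 0

    def lanes_x(self, image_width: float = 810.0) -> Tuple[float, ...]:
        if self.lane_x_positions is not None:
            return tuple(self.lane_x_positions)
        return tuple(image_width * (i + 1) / (self.n_lanes + 1)
                     for i in range(self.n_lanes))

    def validate(self) -> None:
        if self.n_lanes < 1 or self.plants_per_lane < 1:
            raise ValueError("need at least one lane and one plant per lane")
        if not (self.in_lane_spacing_mean > self.in_lane_spacing_jitter >= 0):
            raise ValueError("require spacing > jitter >= 0")
        if self.box_w_mean <= 0 or self.box_h_mean <= 0:
            raise ValueError("box sizes must be positive")
        xs = sorted(self.lanes_x())
        for a, b in zip(xs, xs[1:]):
            if b - a <= self.box_w_mean:
                raise ValueError(
                    f"lanes at x={a} and x={b} overlap within box width "
                    f"{self.box_w_mean}")


@dataclass(frozen=True)
class GroundPlant:
    """One plant's immutable ground position and size."""

    plant_id: int  # persistent ground-truth ID, lane-major
    lane: int
    ordinal: int
    x: float
    y: float  # ground coordinate along the lane direction
    w: float
    h: float


@dataclass(frozen=True)
class MotionProfile:
    """Piecewise-constant camera motion: segments of (n_frames, dy/frame).

    Frame ``t`` is captured at window offset ``sum of the dy of frames
    1..t-1`` (the first frame sits at offset 0), so a forward segment
    followed by its mirror image retraces the same window positions.
    """

    segments: Tuple[Tuple[int, float], ...] = ((200, 6.0),)
    image_width: int = 810
    image_height: int = 1080

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("motion profile must span at least one frame")

    @property
    def n_frames(self) -> int:
        return sum(n for n, _ in self.segments)

    def offsets(self) -> np.ndarray:
        """Window offset of every frame, shape (n_frames,)."""
        steps = np.concatenate([np.full(n, dy) for n, dy in self.segments])
        return np.concatenate([[0.0], np.cumsum(steps[:-1])])

    @staticmethod
    def straight(n_frames: int = 200, dy: float = 6.0, **kw) -> "MotionProfile":
        return MotionProfile(segments=((n_frames, dy),), **kw)

    @staticmethod
    def back_and_forth(n_each: int = 200, dy: float = 6.0, **kw) -> "MotionProfile":
        return MotionProfile(segments=((n_each, dy), (n_each, -dy)), **kw)


@dataclass(frozen=True)
class NoiseSpec:
    """Detection degradation: jitter, misses, false positives."""

    center_sigma: float = 0.0  # px, Gaussian on each center coordinate
    size_sigma: float = 0.0    # px, Gaussian on width and height
    p_miss: float = 0.0        # per-box miss probability
    fp_rate: float = 0.0       # expected false positives per frame (Poisson)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_miss < 1.0):
            raise ValueError("p_miss must lie in [0, 1)")
        if self.center_sigma < 0 or self.size_sigma < 0 or self.fp_rate < 0:
            raise ValueError("noise magnitudes must be >= 0")


def generate_field(spec: FieldSpec, image_width: float = 810.0) -> List[GroundPlant]:
    """Lay out the field; deterministic given ``spec.seed``.

    Ground-truth IDs are lane-major: lane 0 gets 1..P, lane 1 gets P+1..2P.
    In-lane gaps are ``spacing_mean`` plus uniform jitter, so all gaps lie
    within ``spacing_mean +- jitter``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plants: List[GroundPlant] = []
    next_id = 1
    for lane, lx in enumerate(spec.lanes_x(image_width)):
        y = spec.first_plant_y
        for ordinal in range(spec.plants_per_lane):
            if ordinal > 0:
                y += spec.in_lane_spacing_mean + rng.uniform(
                    -spec.in_lane_spacing_jitter, spec.in_lane_spacing_jitter)
            w = spec.box_w_mean + rng.uniform(-spec.box_size_jitter,
                                              spec.box_size_jitter)
            h = spec.box_h_mean + rng.uniform(-spec.box_size_jitter,
                                              spec.box_size_jitter)
            plants.append(GroundPlant(plant_id=next_id, lane=lane,
                                      ordinal=ordinal, x=lx, y=y, w=w, h=h))
            next_id += 1
    return plants


def _clip_box(cx: float, cy: float, w: float, h: float,
              width: float, height: float) -> Optional[Tuple[float, float, float, float]]:
    """Clip a center-form box to [0,width] x [0,height]; None if empty."""
    x1, x2 = max(cx - w / 2, 0.0), min(cx + w / 2, width)
    y1, y2 = max(cy - h / 2, 0.0), min(cy + h / 2, height)
    if x2 - x1 <= 0 or y2 - y1 <= 0:
        return None
    return ((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


def simulate_pass(field: Sequence[GroundPlant], motion: MotionProfile,
                  noise: NoiseSpec = NoiseSpec(),
                  min_visibility: float = 0.25,
                  name: str = "sim") -> Tuple[MOTSequence, MOTSequence]:
    """Render a camera pass over the field into (detections, ground truth).

    A plant enters the ground truth of a frame when at least
    ``min_visibility`` of its box area lies inside the camera window (the
    box is clipped to the window).  Both sequences are deterministic given
    the field and ``noise.seed``.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    W, H = float(motion.image_width), float(motion.image_height)
    det = MOTSequence(image_width=motion.image_width,
                      image_height=motion.image_height, name=f"{name}:det")
    gt = MOTSequence(image_width=motion.image_width,
                     image_height=motion.image_height, name=f"{name}:gt")
    for t, wy in enumerate(motion.offsets(), start=1):
        for p in field:
            cy = p.y - wy
            clipped = _clip_box(p.x, cy, p.w, p.h, W, H)
            if clipped is None:
                continue
            ccx, ccy, cw, ch = clipped
            if cw * ch < min_visibility * p.w * p.h:
                continue
            gt.add(Detection(frame=t, cx=ccx, cy=ccy, w=cw, h=ch,
                             conf=1.0, id=p.plant_id))
            if rng.random() < noise.p_miss:
                continue
            if noise.center_sigma:
                ncx = ccx + rng.normal(0.0, noise.center_sigma)
                ncy = ccy + rng.normal(0.0, noise.center_sigma)
            else:
                ncx, ncy = ccx, ccy
            nw = max(cw + rng.normal(0.0, noise.size_sigma), 4.0) if noise.size_sigma else cw
            nh = max(ch + rng.normal(0.0, noise.size_sigma), 4.0) if noise.size_sigma else ch
            reclipped = _clip_box(ncx, ncy, nw, nh, W, H)
            if reclipped is None:
                continue
            ncx, ncy, nw, nh = reclipped
            det.add(Detection(frame=t, cx=ncx, cy=ncy, w=nw, h=nh, conf=1.0))
        if noise.fp_rate > 0:
            for _ in range(rng.poisson(noise.fp_rate)):
                w = max(rng.normal(100.0, 15.0), 10.0)
                h = max(rng.normal(100.0, 15.0), 10.0)
                cx = rng.uniform(w / 2, W - w / 2)
                cy = rng.uniform(h / 2, H - h / 2)
                det.add(Detection(frame=t, cx=cx, cy=cy, w=w, h=h, conf=0.6))
        det.frames.setdefault(t, [])
        gt.frames.setdefault(t, [])
    return det, gt
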