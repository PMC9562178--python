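"""Neighbor-based geometric identity features.

Plants are fixed to the ground, so the distances from a plant to its in-lane
neighbors and the size ratio between those neighbors are stable signatures of
*which* plant it is, independent of camera translation.  For a middle plant
with center ``(x, y)``, upper neighbor ``(x1, y1, w1, h1)`` and lower
neighbor ``(x2, y2, w2, h2)``, the feature is the 4-vector

    F = [ c1 * sqrt((x1-x)^2 + (y1-y)^2),
          c2 * sqrt((x2-x)^2 + (y2-y)^2),
          cw * w1/w2,
          ch * h1/h2 ]

and two features are compared by plain Euclidean distance.  The weights
balance the pixel-scale distance terms against the order-one ratio terms;
by default the distance weights are set to one over the median in-lane
neighbor spacing of the current frame, which puts all four components on the
same order-one scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import Detection
from .geometry import LaneAssignment

__all__ = [
    "FeatureWeights",
    "PlantFeature",
    "extract_feature",
    "feature_distance",
    "spacing_weights",
    "median_neighbor_spacing",
]


@dataclass(frozen=True)
class FeatureWeights:
    """Weights ``(c1, c2, cw, ch)`` of the feature components; all > 0."""

    c1: float = 1.0
    c2: float = 1.0
    cw: float = 1.0
    ch: float = 1.0

    def __post_init__(self):
        for name in ("c1", "c2", "cw", "ch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"feature weight {name} must be > 0")


@dataclass(frozen=True)
class PlantFeature:
    """The 4-vector ``[d1, d2, wr, hr]`` identifying a middle plant.

    ``d1``/``d2`` are the (weighted) center distances to the upper/lower
    neighbor; ``wr``/``hr`` the (weighted) width and height ratios
    upper/lower.
    """

    d1: float
    d2: float
    wr: float
    hr: float

    def as_tuple(self):
        return (self.d1, self.d2, self.wr, self.hr)


def extract_feature(middle: Detection, upper: Detection, lower: Detection,
                    weights: FeatureWeights = FeatureWeights()) -> PlantFeature:
    """Build the identity feature of ``middle`` from its in-lane neighbors.

    Requires ``upper.cy < middle.cy < lower.cy`` (all three in the same
    lane) and a lower neighbor with positive size.
    """
    if not (upper.cy < middle.cy < lower.cy):
        raise ValueError(
            f"neighbor ordering violated: upper.cy={upper.cy}, "
            f"middle.cy={middle.cy}, lower.cy={lower.cy}")
    if lower.w <= 0 or lower.h <= 0:
        raise ValueError("lower neighbor must have positive width and height")
    d1 = weights.c1 * math.hypot(upper.cx - middle.cx, upper.cy - middle.cy)
    d2 = weights.c2 * math.hypot(lower.cx - middle.cx, lower.cy - middle.cy)
    wr = weights.cw * upper.w / lower.w
    hr = weights.ch * upper.h / lower.h
    return PlantFeature(d1=d1, d2=d2, wr=wr, hr=hr)


def feature_distance(f1: PlantFeature, f2: PlantFeature) -> float:
    """Euclidean distance between two plant features."""
    return math.sqrt(
        (f1.d1 - f2.d1) ** 2 + (f1.d2 - f2.d2) ** 2
        + (f1.wr - f2.wr) ** 2 + (f1.hr - f2.hr) ** 2)


def median_neighbor_spacing(assignment: LaneAssignment) -> float:
    """Median Euclidean distance between consecutive in-lane centers.

    Returns ``nan`` when no lane has two detections.
    """
    gaps = []
    dets = assignment.detections
    for order in assignment.order_in_lane.values():
        for a, b in zip(order, order[1:]):
            gaps.append(math.hypot(dets[b].cx - dets[a].cx,
                                   dets[b].cy - dets[a].cy))
    if not gaps:
        return float("nan")
    gaps.sort()
    n = len(gaps)
    mid = n // 2
    return gaps[mid] if n % 2 else 0.5 * (gaps[mid - 1] + gaps[mid])


def spacing_weights(spacing: float) -> FeatureWeights:
    """Distance-normalizing weights: ``c1 = c2 = 1/spacing``, ``cw = ch = 1``."""
    if not (spacing > 0) or not math.isfinite(spacing):
        raise ValueError(f"spacing must be positive and finite, got {spacing}")
    return FeatureWeights(c1=1.0 / spacing, c2=1.0 / spacing, cw=1.0, ch=1.0)
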