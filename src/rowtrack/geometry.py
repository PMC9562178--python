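"""Crop-row geometry: center line, lane assignment, middle-plant selection.

A nadir camera on a row-following robot sees lanes of plants as near-vertical
columns, so the crop center line is parameterized as ``x = k*y + b`` — x as a
linear function of y — which stays well-conditioned for vertical columns
(where a conventional ``y = m*x + c`` fit would blow up).  Two detections lie
in the same lane of a two-lane field iff their signed residuals
``r = k*cy + b - cx`` have the same sign; for more lanes the residuals are
clustered in 1-D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io import Detection

__all__ = [
    "CenterLine",
    "LaneAssignment",
    "DegenerateGeometryError",
    "fit_center_line",
    "split_lanes",
    "classify_middle_plants",
]


class DegenerateGeometryError(ValueError):
    """Detection layout does not admit the requested geometric construction."""


@dataclass(frozen=True)
class CenterLine:
    """The fitted crop center line ``x = k*y + b``.

    ``k`` is the slope in pixels of x per pixel of y (dimensionless),
    ``b`` the intercept in pixels.
    """

    k: float
    b: float

    def x_at(self, y: float) -> float:
        return self.k * y + self.b

    def residual(self, cx: float, cy: float) -> float:
        """Signed residual ``k*cy + b - cx`` of a center point."""
        return self.k * cy + self.b - cx


@dataclass
class LaneAssignment:
    """Lane membership and in-lane ordering of one frame's detections.

    ``lane_of[i]`` is the lane index of detection ``i`` (indices refer to the
    input list); ``order_in_lane[lane]`` lists detection indices sorted by
    ``cy`` ascending (ties broken by ``cx`` ascending).
    """

    detections: List[Detection]
    lane_of: Dict[int, int] = field(default_factory=dict)
    order_in_lane: Dict[int, List[int]] = field(default_factory=dict)

    @property
    def n_lanes(self) -> int:
        return len(self.order_in_lane)


def fit_center_line(centers: Sequence[Tuple[float, float]]) -> CenterLine:
    """Least-squares fit of ``x = k*y + b`` through box centers.

    Requires at least two centers with at least two distinct ``cy`` values;
    exact on collinear input.
    """
    if len(centers) < 2:
        raise DegenerateGeometryError(
            f"need >= 2 centers to fit a line, got {len(centers)}")
    arr = np.asarray(centers, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(y) == 0:
        raise DegenerateGeometryError(
            "all centers share the same cy; the column line x = k*y + b "
            "cannot be parameterized")
    # Normal equations of the regression of x on y.
    k, b = np.polyfit(y, x, 1)
    return CenterLine(k=float(k), b=float(b))


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means: quantile initialization + Lloyd iterations."""
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(values, qs)
    labels = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        dist = np.abs(values[:, None] - centers[None, :])
        new_labels = np.argmin(dist, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            sel = values[labels == j]
            if len(sel):
                centers[j] = sel.mean()
    # relabel so lane 0 has the largest residual mean (leftmost lane: larger
    # residual r = k*cy + b - cx means smaller cx)
    order = np.argsort(-centers)
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels])


def split_lanes(dets: Sequence[Detection], line: CenterLine,
                n_lanes: int = 2) -> LaneAssignment:
    """Partition detections into lanes by their signed center-line residuals.

    For two lanes, two detections share a lane iff the product of their
    signed residuals is positive; a residual of exactly zero is resolved to
    the lane of the nearest (by absolute residual) nonzero-residual
    detection.  For more than two lanes, residuals are clustered with a
    deterministic 1-D k-means.  Lane 0 is the leftmost lane (smallest cx).
    Within each lane, detections are ordered by ``cy`` ascending, ties by
    ``cx``.
    """
    if n_lanes < 1:
        raise ValueError(f"n_lanes must be >= 1, got {n_lanes}")
    dets = list(dets)
    assignment = LaneAssignment(detections=dets)
    if not dets:
        assignment.order_in_lane = {i: [] for i in range(n_lanes)}
        return assignment
    res = np.array([line.residual(d.cx, d.cy) for d in dets])

    if n_lanes == 1:
        labels = np.zeros(len(dets), dtype=int)
    elif n_lanes == 2:
        labels = np.where(res > 0, 0, 1)  # r > 0 => cx left of line => lane 0
        zero = np.flatnonzero(res == 0)
        nonzero = np.flatnonzero(res != 0)
        for i in zero:
            if len(nonzero) == 0:
                labels[i] = 0
            else:
                j = nonzero[np.argmin(np.abs(res[nonzero] - res[i]))]
                labels[i] = labels[j]
    else:
        if len(np.unique(res)) < n_lanes:
            raise DegenerateGeometryError(
                f"cannot split {len(np.unique(res))} distinct residuals into "
                f"{n_lanes} lanes")
        labels = _kmeans_1d(res, n_lanes)

    assignment.lane_of = {i: int(l) for i, l in enumerate(labels)}
    assignment.order_in_lane = {lane: [] for lane in range(n_lanes)}
    for lane in range(n_lanes):
        members = [i for i in range(len(dets)) if labels[i] == lane]
        members.sort(key=lambda i: (dets[i].cy, dets[i].cx))
        assignment.order_in_lane[lane] = members
    return assignment


def classify_middle_plants(assignment: LaneAssignment) -> Dict[str, List[int]]:
    """Partition each lane's detections into middle and edge plants.

    Within each lane (ordered by ``cy``), the first detection is the top
    edge, the last the bottom edge, everything in between is a middle plant
    — only middle plants have both in-lane neighbors and hence an
    extractable identity feature.  A lane with one detection contributes it
    to the top edge; a lane with two has no middle plants.  Returns a dict
    with keys ``middle``, ``top_edge``, ``bottom_edge`` holding disjoint
    detection-index lists covering every detection exactly once.
    """
    out: Dict[str, List[int]] = {"middle": [], "top_edge": [], "bottom_edge": []}
    for lane in sorted(assignment.order_in_lane):
        order = assignment.order_in_lane[lane]
        if not order:
            continue
        if len(order) == 1:
            out["top_edge"].append(order[0])
            continue
        out["top_edge"].append(order[0])
        out["bottom_edge"].append(order[-1])
        out["middle"].extend(order[1:-1])
    return out
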