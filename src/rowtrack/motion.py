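"""Constant-velocity Kalman box prediction and IOU.

Plants are immobile on the ground; all apparent motion is camera-induced
translation.  The per-track state is therefore
``(cx, cy, w, h, vcx, vcy)`` — box center, box size, and center velocity in
pixels per frame — with sizes modeled as quasi-constant (no size velocity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Detection

__all__ = ["KalmanParams", "KalmanTrackState", "kf_initiate", "kf_predict",
           "kf_update", "iou"]

_DIM = 6  # (cx, cy, w, h, vcx, vcy)


@dataclass(frozen=True)
class KalmanParams:
    """Noise model of the constant-velocity filter.

    ``sigma_meas``: measurement std on each observed component (px);
    ``sigma_pos``: per-frame process std on position/size (px);
    ``sigma_vel``: per-frame process std on velocity (px/frame);
    ``init_vel_std``: velocity std of a freshly initiated track (px/frame).
    Defaults suit 30 Hz nadir imagery where the inter-frame shift is a few
    pixels.
    """

    sigma_meas: float = 1.0
    sigma_pos: float = 1.0
    sigma_vel: float = 10.0
    init_vel_std: float = 10.0


@dataclass
class KalmanTrackState:
    """Gaussian belief over one plant's box and image velocity."""

    mean: np.ndarray
    covariance: np.ndarray
    age: int = 0  # frames since last measurement update

    @property
    def box(self) -> tuple:
        cx, cy, w, h = self.mean[:4]
        return (float(cx), float(cy), float(max(w, 1.0)), float(max(h, 1.0)))


def _transition(dt: float) -> np.ndarray:
    F = np.eye(_DIM)
    F[0, 4] = dt
    F[1, 5] = dt
    return F


_H = np.hstack([np.eye(4), np.zeros((4, 2))])


def kf_initiate(obs: Detection, params: KalmanParams = KalmanParams()) -> KalmanTrackState:
    """Start a track at an observed box with zero velocity and inflated
    velocity uncertainty."""
    mean = np.array([obs.cx, obs.cy, obs.w, obs.h, 0.0, 0.0])
    cov = np.diag([params.sigma_meas ** 2] * 4
                  + [params.init_vel_std ** 2] * 2).astype(float)
    return KalmanTrackState(mean=mean, covariance=cov, age=0)


def kf_predict(state: KalmanTrackState, params: KalmanParams = KalmanParams(),
               dt: float = 1.0) -> KalmanTrackState:
    """Advance the belief ``dt`` frames under constant velocity (in place).

    Returns the same state object; ``state.box`` is the predicted box.
    """
    F = _transition(dt)
    Q = np.diag([params.sigma_pos ** 2] * 4 + [params.sigma_vel ** 2] * 2) * max(dt, 1.0)
    state.mean = F @ state.mean
    state.covariance = F @ state.covariance @ F.T + Q
    state.age += 1
    return state


def kf_update(state: KalmanTrackState, obs: Detection,
              params: KalmanParams = KalmanParams()) -> KalmanTrackState:
    """Standard Kalman correction with an observed box (in place)."""
    z = np.array([obs.cx, obs.cy, obs.w, obs.h], dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite observation: {z}")
    R = np.eye(4) * params.sigma_meas ** 2
    S = _H @ state.covariance @ _H.T + R
    K = state.covariance @ _H.T @ np.linalg.solve(S, np.eye(4))
    innovation = z - _H @ state.mean
    state.mean = state.mean + K @ innovation
    # Joseph form keeps the covariance symmetric PSD.
    IKH = np.eye(_DIM) - K @ _H
    state.covariance = IKH @ state.covariance @ IKH.T + K @ R @ K.T
    state.covariance = 0.5 * (state.covariance + state.covariance.T)
    state.age = 0
    return state


def iou(box_a: tuple, box_b: tuple) -> float:
    """Intersection over union of two center-form boxes ``(cx, cy, w, h)``.

    Returns a value in ``[0, 1]``; 0 for disjoint boxes.
    """
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive sizes")
    ix = min(ax + aw / 2, bx + bw / 2) - max(ax - aw / 2, bx - bw / 2)
    iy = min(ay + ah / 2, by + bh / 2) - max(ay - ah / 2, by - bh / 2)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return float(inter / union)
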