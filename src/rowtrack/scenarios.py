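"""Canonical benchmark scenarios for the tracker.

These fix one coherent set of study conditions used by the test suite and
the reproduction script: a two-lane field dense enough that a 200-frame
pass at ~6 px/frame sweeps every plant through the view, a straight regime,
a back-and-forth (B&F) regime in which every plant leaves the view and
re-enters during the reverse leg, and a noisy B&F regime with center/size
jitter and missed detections.  The candidate-window radii of the tracker
configuration are sized from the number of plants simultaneously visible
(window height plus box height over in-lane spacing, plus margin), per the
window's purpose of covering all simultaneously visible plants.
"""

from __future__ import annotations

import math
from typing import Tuple

from .association import AssociationConfig
from .io import MOTSequence
from .simulate import FieldSpec, MotionProfile, NoiseSpec, generate_field, simulate_pass
from .tracker import TrackerConfig

__all__ = ["benchmark_field", "benchmark_tracker_config",
           "straight_pass", "back_and_forth_pass", "noisy_back_and_forth"]

_SPACING = 100.0
_IMAGE_W, _IMAGE_H = 810, 1080
_BOX = 80.0
_DY = 6.0


def benchmark_field(plants_per_lane: int = 20, seed: int = 0) -> FieldSpec:
    """Two-lane field fully traversable in 200 frames at 6 px/frame."""
    return FieldSpec(
        n_lanes=2, plants_per_lane=plants_per_lane,
        in_lane_spacing_mean=_SPACING, in_lane_spacing_jitter=10.0,
        box_w_mean=_BOX, box_h_mean=_BOX, box_size_jitter=6.0,
        first_plant_y=150.0, seed=seed)


def benchmark_tracker_config(iou_only: bool = False) -> TrackerConfig:
    visible = math.ceil((_IMAGE_H + _BOX) / _SPACING) + 2
    assoc = AssociationConfig(x1=visible, x2=visible)
    return TrackerConfig(n_lanes=2, association=assoc, iou_only=iou_only)


def straight_pass(n_frames: int = 200, plants_per_lane: int = 20,
                  field_seed: int = 0, noise: NoiseSpec = NoiseSpec()
                  ) -> Tuple[MOTSequence, MOTSequence]:
    """Forward-only regime: (detections, ground truth)."""
    field = generate_field(benchmark_field(plants_per_lane, field_seed), _IMAGE_W)
    motion = MotionProfile.straight(n_frames, _DY, image_width=_IMAGE_W,
                                    image_height=_IMAGE_H)
    return simulate_pass(field, motion, noise, name="straight")


def back_and_forth_pass(n_each: int = 200, plants_per_lane: int = 20,
                        field_seed: int = 0, noise: NoiseSpec = NoiseSpec()
                        ) -> Tuple[MOTSequence, MOTSequence]:
    """Forward-then-reverse regime: every plant exits and re-enters."""
    field = generate_field(benchmark_field(plants_per_lane, field_seed), _IMAGE_W)
    motion = MotionProfile.back_and_forth(n_each, _DY, image_width=_IMAGE_W,
                                          image_height=_IMAGE_H)
    return simulate_pass(field, motion, noise, name="bf")


def noisy_back_and_forth(noise_seed: int, field_seed: int = 0
                         ) -> Tuple[MOTSequence, MOTSequence]:
    """B&F regime with detector-like degradation: 2 px center jitter,
    2 px size jitter, 5% missed detections."""
    noise = NoiseSpec(center_sigma=2.0, size_sigma=2.0, p_miss=0.05,
                      fp_rate=0.0, seed=noise_seed)
    return back_and_forth_pass(noise=noise, field_seed=field_seed)
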