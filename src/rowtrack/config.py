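"""YAML experiment configuration, schema checking, and the experiment driver.

One YAML file with sections ``field`` / ``motion`` / ``noise`` / ``tracker``
describes a complete simulate-track-evaluate run.  ``run_experiment``
materializes it into an output directory holding ``det.txt``, ``gt.txt``,
``result.txt``, ``report.json`` and a ``manifest.json`` snapshot from which
the run is reconstructible; rerunning the same config reproduces
``report.json`` exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from . import __version__
from .association import AssociationConfig
from .features import FeatureWeights
from .io import write_mot_file
from .metrics import evaluate
from .motion import KalmanParams
from .simulate import FieldSpec, MotionProfile, NoiseSpec, generate_field, simulate_pass
from .tracker import TrackerConfig, run_sequence

__all__ = ["ConfigError", "load_experiment_config", "run_experiment",
           "tracker_config_from_dict", "tracker_config_to_dict"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


def _check_keys(section: str, d: Dict[str, Any], allowed) -> None:
    bad = sorted(set(d) - set(allowed))
    if bad:
        raise ConfigError(f"unknown keys in section {section!r}: {bad}; "
                          f"allowed: {sorted(allowed)}")


def _dataclass_from(section: str, cls, d: Dict[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, d, fields)
    return cls(**d)


def tracker_config_from_dict(d: Dict[str, Any]) -> TrackerConfig:
    d = dict(d)
    _check_keys("tracker", d, {"n_lanes", "min_conf", "weights", "association",
                               "kalman", "patience", "iou_only",
                               "iou_only_min_iou", "edge_min_iou"})
    weights = d.pop("weights", None)
    if weights is not None:
        weights = _dataclass_from("tracker.weights", FeatureWeights, weights)
    assoc = _dataclass_from("tracker.association", AssociationConfig,
                            d.pop("association", {}) or {})
    kalman = _dataclass_from("tracker.kalman", KalmanParams,
                             d.pop("kalman", {}) or {})
    return TrackerConfig(weights=weights, association=assoc, kalman=kalman, **d)


def tracker_config_to_dict(cfg: TrackerConfig) -> Dict[str, Any]:
    d = dataclasses.asdict(cfg)
    return d


def _motion_from_dict(d: Dict[str, Any]) -> MotionProfile:
    d = dict(d)
    _check_keys("motion", d, {"regime", "n_frames", "dy", "image_width",
                              "image_height", "segments"})
    kw = {}
    for k in ("image_width", "image_height"):
        if k in d:
            kw[k] = d[k]
    if "segments" in d:
        return MotionProfile(segments=tuple(tuple(s) for s in d["segments"]), **kw)
    regime = d.get("regime", "straight")
    n = int(d.get("n_frames", 200))
    dy = float(d.get("dy", 6.0))
    if regime == "straight":
        return MotionProfile.straight(n, dy, **kw)
    if regime == "back_and_forth":
        return MotionProfile.back_and_forth(n, dy, **kw)
    raise ConfigError(f"unknown motion regime {regime!r}; "
                      f"expected straight or back_and_forth")


def load_experiment_config(path) -> Dict[str, Any]:
    """Parse and validate an experiment YAML into constructed objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys("<root>", raw, {"name", "field", "motion", "noise", "tracker",
                                "min_visibility"})
    return {
        "name": raw.get("name", Path(path).stem),
        "field": _dataclass_from("field", FieldSpec, raw.get("field", {}) or {}),
        "motion": _motion_from_dict(raw.get("motion", {}) or {}),
        "noise": _dataclass_from("noise", NoiseSpec, raw.get("noise", {}) or {}),
        "tracker": tracker_config_from_dict(raw.get("tracker", {}) or {}),
        "min_visibility": float(raw.get("min_visibility", 0.25)),
        "_raw": raw,
    }


def write_seqinfo(path, name: str, motion: MotionProfile,
                  frame_rate: int = 30) -> None:
    Path(path).write_text(
        "[Sequence]\n"
        f"name={name}\n"
        f"imDir=img1\n"
        f"frameRate={frame_rate}\n"
        f"seqLength={motion.n_frames}\n"
        f"imWidth={motion.image_width}\n"
        f"imHeight={motion.image_height}\n"
        "imExt=.jpg\n")


def run_experiment(config_path, out_dir) -> Path:
    """Simulate, track, and evaluate one configured experiment.

    Returns the output directory containing det.txt, gt.txt, result.txt,
    report.json, seqinfo.ini and manifest.json.
    """
    cfg = load_experiment_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    field = generate_field(cfg["field"], cfg["motion"].image_width)
    det, gt = simulate_pass(field, cfg["motion"], cfg["noise"],
                            min_visibility=cfg["min_visibility"],
                            name=cfg["name"])
    result = run_sequence(det, cfg["tracker"])
    report = evaluate(gt, result)

    write_mot_file(det, out / "det.txt")
    write_mot_file(gt, out / "gt.txt")
    write_mot_file(result, out / "result.txt")
    write_seqinfo(out / "seqinfo.ini", cfg["name"], cfg["motion"])
    (out / "report.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n")
    manifest = {
        "tool": "rowtrack",
        "version": __version__,
        "config": cfg["_raw"],
        "config_path": str(Path(config_path).resolve()),
        "seeds": {"field": cfg["field"].seed, "noise": cfg["noise"].seed},
        "outputs": ["det.txt", "gt.txt", "result.txt", "report.json",
                    "seqinfo.ini"],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
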