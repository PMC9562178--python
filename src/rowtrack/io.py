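"""Reading and writing MOTChallenge-style text files.

The MOTChallenge dialect is a plain CSV with one bounding box per line::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

The trailing three fields are world-coordinate placeholders and are always
written as ``-1``.  Detection files carry ``id = -1`` (unassigned); ground
truth and tracker-output files carry positive IDs.  Internally boxes are kept
in center form ``(cx, cy, w, h)`` because every downstream computation
(center-line fit, neighbor distances, Kalman state) works on centers.
Coordinates are continuous pixels, origin at the image top-left corner, y
increasing downward; corner offsets are taken as exact real values with no
0-/1-based pixel adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Optional

__all__ = [
    "Detection",
    "MOTSequence",
    "MOTParseError",
    "read_mot_file",
    "write_mot_file",
]


class MOTParseError(ValueError):
    """A line of a MOT text file could not be parsed or validated."""


@dataclass
class Detection:
    """One axis-aligned bounding box observed in one frame.

    Attributes
    ----------
    frame : int
        1-based frame index.
    cx, cy : float
        Box center in pixels.
    w, h : float
        Box width and height in pixels, strictly positive.
    conf : float
        Detection confidence in ``[0, 1]``.
    id : int or None
        Plant identity (``>= 1``) or ``None`` when unassigned.
    """

    frame: int
    cx: float
    cy: float
    w: float
    h: float
    conf: float = 1.0
    id: Optional[int] = None

    def validate(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame index must be >= 1, got {self.frame}")
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.conf}")
        if self.id is not None and self.id < 1:
            raise ValueError(f"assigned IDs must be >= 1, got {self.id}")

    @property
    def bb_left(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def bb_top(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def box(self) -> tuple:
        """Center-form box ``(cx, cy, w, h)``."""
        return (self.cx, self.cy, self.w, self.h)

    def with_id(self, plant_id: Optional[int]) -> "Detection":
        return replace(self, id=plant_id)


@dataclass
class MOTSequence:
    """An ordered collection of frames of detections.

    ``frames`` maps 1-based frame index to the list of detections observed in
    that frame.  Round-trippable to MOTChallenge text files.
    """

    frames: Dict[int, List[Detection]] = field(default_factory=dict)
    image_width: int = 810
    image_height: int = 1080
    name: str = "sequence"

    def add(self, det: Detection) -> None:
        det.validate()
        bucket = self.frames.setdefault(det.frame, [])
        if det.id is not None and any(d.id == det.id for d in bucket):
            raise ValueError(f"duplicate ID {det.id} in frame {det.frame}")
        bucket.append(det)

    def frame_indices(self) -> List[int]:
        return sorted(self.frames)

    def __iter__(self) -> Iterator[tuple]:
        for f in self.frame_indices():
            yield f, self.frames[f]

    def n_detections(self) -> int:
        return sum(len(v) for v in self.frames.values())

    def ids(self) -> set:
        return {d.id for dets in self.frames.values() for d in dets if d.id is not None}

    def validate(self) -> None:
        for f, dets in self.frames.items():
            if f < 1:
                raise ValueError(f"frame indices must be positive, got {f}")
            seen = set()
            for d in dets:
                d.validate()
                if d.frame != f:
                    raise ValueError(f"detection frame {d.frame} stored under frame {f}")
                if d.id is not None:
                    if d.id in seen:
                        raise ValueError(f"duplicate ID {d.id} in frame {f}")
                    seen.add(d.id)


def _fmt(x: float) -> str:
    """Format a number so that integral values print without a decimal point."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def read_mot_file(path, kind: str = "det", image_width: int = 810,
                  image_height: int = 1080) -> MOTSequence:
    """Read a MOTChallenge text file into a :class:`MOTSequence`.

    Parameters
    ----------
    path : path-like
        File to read.
    kind : {"det", "gt", "result"}
        File flavor; affects only the sequence name.  ``id = -1`` always maps
        to unassigned, and the confidence column is read for every flavor.
    """
    if kind not in ("det", "gt", "result"):
        raise ValueError(f"kind must be det, gt or result, got {kind!r}")
    path = Path(path)
    seq = MOTSequence(image_width=image_width, image_height=image_height,
                      name=f"{path.stem}:{kind}")
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MOTParseError(
                    f"{path}:{lineno}: expected >= 7 comma-separated fields, "
                    f"got {len(parts)}: {line!r}")
            try:
                frame = int(float(parts[0]))
                obj_id = int(float(parts[1]))
                left, top, w, h, conf = (float(p) for p in parts[2:7])
            except ValueError as exc:
                raise MOTParseError(f"{path}:{lineno}: non-numeric field: {line!r}") from exc
            if w <= 0 or h <= 0:
                raise MOTParseError(
                    f"{path}:{lineno}: non-positive box size w={w}, h={h}")
            det = Detection(frame=frame, cx=left + w / 2.0, cy=top + h / 2.0,
                            w=w, h=h, conf=conf,
                            id=None if obj_id == -1 else obj_id)
            try:
                seq.add(det)
            except ValueError as exc:
                raise MOTParseError(f"{path}:{lineno}: {exc}") from exc
    return seq


def write_mot_file(seq: MOTSequence, path) -> Path:
    """Write a :class:`MOTSequence` as a MOTChallenge text file.

    Frames are written in ascending order; within a frame, assigned IDs
    ascending (unassigned lines last, in insertion order).  Returns the path.
    """
    path = Path(path)
    lines = []
    for f in seq.frame_indices():
        dets = sorted(seq.frames[f],
                      key=lambda d: (d.id is None, d.id if d.id is not None else 0))
        for d in dets:
            d.validate()
            obj_id = -1 if d.id is None else d.id
            lines.append(",".join([
                str(f), str(obj_id), _fmt(d.bb_left), _fmt(d.bb_top),
                _fmt(d.w), _fmt(d.h), _fmt(d.conf), "-1", "-1", "-1"]))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
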