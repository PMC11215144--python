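"""File formats: MOT-dialect CSV, LabelMe JSON, YAML configuration.

The on-disk detection/track format is the MOT-challenge CSV dialect::

    frame, id, x, y, w, h, conf

with 1-based frame indices and top-left-corner box coordinates (0-based,
half-open pixel coordinates). Internally frames are 0-based and boxes are
center-form; this module is the single conversion boundary. Raw detections
carry id −1. There is no header; lines starting with ``#`` are ignored on
read. Floats are written in shortest round-trip form, so read → write is
byte-stable on canonical files and write → read loses nothing.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable

import yaml

from .counter import CounterConfig
from .detections import FrameDetections
from .geometry import BoundingBox, InvalidBoxError
from .simulate import SceneConfig, SceneTruth

__all__ = [
    "MotRecord",
    "ParseError",
    "read_mot",
    "write_mot",
    "read_detections",
    "write_detections",
    "write_truth",
    "read_labelme",
    "write_labelme",
    "load_config",
    "scene_config_from_dict",
    "counter_config_from_dict",
]


class ParseError(ValueError):
    """A malformed input file; the message carries the line number."""


@dataclasses.dataclass(frozen=True)
class MotRecord:
    """One CSV row: 1-based frame, track id (−1 for raw detections),
    top-left corner, size, confidence."""

    frame: int
    id: int
    x: float
    y: float
    w: float
    h: float
    conf: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"file frame indices are 1-based, got {self.frame}")
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"non-positive box size w={self.w}, h={self.h}")

    def to_box(self) -> BoundingBox:
        return BoundingBox.from_xywh(self.x, self.y, self.w, self.h, self.conf)

    @classmethod
    def from_box(cls, frame0: int, box: BoundingBox, id: int = -1) -> "MotRecord":
        return cls(frame0 + 1, id, box.x1, box.y1, box.w, box.h, box.conf)


def _fmt(x: float) -> str:
    # shortest exact decimal; integers without trailing ".0" noise kept as repr
    return repr(float(x)) if not float(x).is_integer() else str(int(x))


def read_mot(path: str | Path) -> list[MotRecord]:
    records: list[MotRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if len(row) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 fields, got {len(row)}")
            try:
                frame, tid = int(row[0]), int(row[1])
                x, y, w, h = (float(v) for v in row[2:6])
                conf = float(row[6]) if len(row) > 6 else 1.0
                records.append(MotRecord(frame, tid, x, y, w, h, conf))
            except (ValueError, InvalidBoxError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_mot(path: str | Path, records: Iterable[MotRecord]) -> None:
    with open(path, "w", newline="") as fh:
        for r in records:
            fh.write(
                f"{r.frame},{r.id},{_fmt(r.x)},{_fmt(r.y)},"
                f"{_fmt(r.w)},{_fmt(r.h)},{_fmt(r.conf)}\n"
            )


def read_detections(path: str | Path) -> list[FrameDetections]:
    """Read a MOT CSV as a dense 0-based frame stream.

    Frames are grouped in ascending order starting at file frame 1; frames
    with no records appear as empty.
    """
    records = read_mot(path)
    if not records:
        return []
    n_frames = max(r.frame for r in records)
    per_frame: list[list[BoundingBox]] = [[] for _ in range(n_frames)]
    for r in records:
        per_frame[r.frame - 1].append(r.to_box())
    return [
        FrameDetections(frame=i, boxes=tuple(boxes))
        for i, boxes in enumerate(per_frame)
    ]


def write_detections(path: str | Path, frames: Iterable[FrameDetections]) -> None:
    """Write a detection stream as MOT CSV with id −1."""
    write_mot(
        path,
        (
            MotRecord.from_box(fd.frame, box)
            for fd in frames
            for box in fd.boxes
        ),
    )


def write_truth(path: str | Path, truth: SceneTruth) -> None:
    """Write simulator ground truth as MOT CSV with true object ids."""
    write_mot(
        path,
        (
            MotRecord.from_box(t, tb.box, id=tb.object_id)
            for t, entries in enumerate(truth.frames)
            for tb in entries
        ),
    )


def read_labelme(path: str | Path, warn=None) -> list[BoundingBox]:
    """Read rectangle shapes from a LabelMe JSON annotation file.

    Non-rectangle shapes are skipped; ``warn`` (default: logging) is called
    with a message for each skipped shape.
    """
    import logging

    warn = warn or logging.getLogger(__name__).warning
    with open(path) as fh:
        doc = json.load(fh)
    try:
        shapes = doc["shapes"]
    except (TypeError, KeyError) as exc:
        raise ParseError(f"{path}: missing 'shapes' field") from exc
    boxes: list[BoundingBox] = []
    for i, shape in enumerate(shapes):
        try:
            kind = shape["shape_type"]
            points = shape["points"]
        except (TypeError, KeyError) as exc:
            raise ParseError(f"{path}: shape {i} missing required fields") from exc
        if kind != "rectangle":
            warn(f"{path}: skipping non-rectangle shape {i} ({kind})")
            continue
        (xa, ya), (xb, yb) = points
        boxes.append(
            BoundingBox.from_corners(
                min(xa, xb), min(ya, yb), max(xa, xb), max(ya, yb)
            )
        )
    return boxes


def write_labelme(
    path: str | Path,
    boxes: Iterable[BoundingBox],
    image_path: str = "",
    image_size: tuple[int, int] | None = None,
) -> None:
    """Write boxes as a minimal LabelMe JSON document (rectangle shapes)."""
    w, h = image_size if image_size else (0, 0)
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": "ear",
                "points": [[b.x1, b.y1], [b.x2, b.y2]],
                "group_id": None,
                "shape_type": "rectangle",
                "flags": {},
            }
            for b in boxes
        ],
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": h,
        "imageWidth": w,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict (empty file → {})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return doc


def _build(cls, base: dict, overrides: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    merged = {k: v for k, v in base.items() if k in known}
    merged.update({k: v for k, v in overrides.items() if v is not None and k in known})
    for key in ("frame_size", "object_w_range", "object_h_range"):
        if key in merged and isinstance(merged[key], list):
            merged[key] = tuple(merged[key])
    return cls(**merged)


def scene_config_from_dict(base: dict, **overrides) -> SceneConfig:
    """Build a SceneConfig from a config mapping; keyword overrides win."""
    return _build(SceneConfig, base, overrides)


def counter_config_from_dict(base: dict, **overrides) -> CounterConfig:
    """Build a CounterConfig from a config mapping; keyword overrides win."""
    return _build(CounterConfig, base, overrides)
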