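"""Data model and readers/writers for detection streams, annotations and events.

Conventions
-----------
* Pixel coordinates are 0-based with the origin at the top-left corner,
  x rightward and y downward; a bounding box is given by its top-left
  (x1, y1) and bottom-right (x2, y2) corners.
* Frame timing: ``time_seconds = frame_index / fps``.  Intervals over frames
  are half-open ``[start_frame, end_frame)``.
* Two on-disk dialects for detection streams: JSONL (one metadata record,
  then one record per frame) and long-format CSV (one detection per row,
  metadata in a ``#``-prefixed header line).  Confidence is stored at full
  precision.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Closed label vocabulary of the upstream object detector.
LABELS = frozenset(
    {"Pig-Standing", "Pig-Laying", "Pig-Head", "Water-Faucet", "Keeper", "Feces"}
)


class FormatError(ValueError):
    """A file is structurally unreadable (missing metadata, bad dialect)."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


def _parse_clock(text: str) -> time:
    for fmt in ("%H:%M:%S", "%H:%M", "%H:%M:%S.%f"):
        try:
            return datetime.strptime(text, fmt).time()
        except ValueError:
            continue
    raise FormatError(f"unparseable clock time: {text!r}")


def clock_at(session_start: time, offset_s: float) -> time:
    """Clock time ``offset_s`` seconds after the session start (wraps at 24 h)."""
    base = datetime(2000, 1, 1, session_start.hour, session_start.minute,
                    session_start.second, session_start.microsecond)
    return (base + timedelta(seconds=float(offset_s))).time()


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, corners (x1, y1) top-left and (x2, y2) bottom-right."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValidationError(
                f"degenerate box: ({self.x1},{self.y1},{self.x2},{self.y2})"
            )
        if min(self.x1, self.y1) < 0:
            raise ValidationError("box coordinates must be non-negative")

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    def within(self, width: float, height: float) -> bool:
        return self.x2 <= width and self.y2 <= height

    def as_list(self) -> list[float]:
        return [self.x1, self.y1, self.x2, self.y2]


@dataclass(frozen=True)
class Detection:
    """One detector output: a labelled, scored box on one frame."""

    frame_index: int
    label: str
    confidence: float
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame index: {self.frame_index}")
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r}; expected one of {sorted(LABELS)}"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class DetectionStream:
    """Ordered per-frame detections plus the scene metadata needed downstream.

    ``d_diag`` (frame diagonal in pixels) normalizes all centroid distances,
    so ``frame_width``/``frame_height`` are mandatory metadata.
    """

    frame_width: int
    frame_height: int
    fps: float
    session_start: time
    n_frames: int
    detections: list[Detection] = field(default_factory=list)
    pen_id: str = "pen"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValidationError("frame dimensions must be positive")
        if self.n_frames < 0:
            raise ValidationError("n_frames must be non-negative")
        for det in self.detections:
            if det.frame_index >= self.n_frames:
                raise ValidationError(
                    f"frame_index {det.frame_index} outside [0, {self.n_frames})"
                )
        idx = [d.frame_index for d in self.detections]
        if any(b < a for a, b in zip(idx, idx[1:])):
            warnings.warn("detections out of frame order; repairing with stable sort")
            self.detections.sort(key=lambda d: d.frame_index)

    @property
    def d_diag(self) -> float:
        return math.hypot(self.frame_width, self.frame_height)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def by_frame(self) -> dict[int, list[Detection]]:
        frames: dict[int, list[Detection]] = {}
        for det in self.detections:
            frames.setdefault(det.frame_index, []).append(det)
        return frames


@dataclass
class GroundTruthTrack:
    """Per-frame binary drinking labels aligned to a stream's frame indices."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 1:
            raise ValidationError("track must be one-dimensional")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("track labels must be 0 or 1")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class DrinkingEvent:
    """A contiguous run of proximity-flagged frames, i.e. one faucet visit.

    Frames are half-open ``[start_frame, end_frame)``; the duration is
    ``(end_frame - start_frame) / fps`` seconds.
    """

    start_frame: int
    end_frame: int
    fps: float
    faucet_id: int
    start_clock: time | None = None
    max_p: float = float("nan")
    mean_p: float = float("nan")
    pen_id: str = "pen"

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValidationError("event must span at least one frame")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")

    @property
    def start_s(self) -> float:
        return self.start_frame / self.fps

    @property
    def end_s(self) -> float:
        return self.end_frame / self.fps

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps

    @property
    def start_hour(self) -> int | None:
        return None if self.start_clock is None else self.start_clock.hour


# ---------------------------------------------------------------------------
# Detection streams
# ---------------------------------------------------------------------------

_META_KEYS = ("frame_width", "frame_height", "fps", "session_start", "n_frames")


def _stream_meta(stream: DetectionStream) -> dict:
    return {
        "frame_width": stream.frame_width,
        "frame_height": stream.frame_height,
        "fps": stream.fps,
        "session_start": stream.session_start.isoformat(),
        "n_frames": stream.n_frames,
        "pen_id": stream.pen_id,
    }


def _build_stream(meta: dict, detections: list[Detection]) -> DetectionStream:
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"metadata record missing keys: {missing}")
    return DetectionStream(
        frame_width=int(meta["frame_width"]),
        frame_height=int(meta["frame_height"]),
        fps=float(meta["fps"]),
        session_start=_parse_clock(str(meta["session_start"])),
        n_frames=int(meta["n_frames"]),
        detections=detections,
        pen_id=str(meta.get("pen_id", "pen")),
    )


def write_detection_stream(stream: DetectionStream, path: str | Path,
                           format: str = "jsonl") -> None:
    """Write a stream in the JSONL or long-CSV dialect."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w") as fh:
            fh.write(json.dumps({"meta": _stream_meta(stream)}) + "\n")
            for frame, dets in sorted(stream.by_frame().items()):
                rec = {
                    "frame": frame,
                    "detections": [
                        {"label": d.label, "conf": d.confidence, "box": d.box.as_list()}
                        for d in dets
                    ],
                }
                fh.write(json.dumps(rec) + "\n")
    elif format == "csv":
        meta = _stream_meta(stream)
        with path.open("w", newline="") as fh:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "label", "confidence", "x1", "y1", "x2", "y2"])
            for d in stream.detections:
                writer.writerow([d.frame_index, d.label, repr(d.confidence),
                                 *(repr(v) for v in d.box.as_list())])
    else:
        raise ValueError(f"unknown format {format!r}")


def read_detection_stream(path: str | Path, format: str | None = None) -> DetectionStream:
    """Read and validate a detection stream (JSONL or CSV, inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _detection_from_record(frame: int, rec: dict, lineno: int) -> Detection:
    try:
        box = BoundingBox(*map(float, rec["box"]))
        return Detection(frame_index=frame, label=rec["label"],
                         confidence=float(rec["conf"]), box=box)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from exc


def _read_jsonl(path: Path) -> DetectionStream:
    detections: list[Detection] = []
    meta: dict | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "meta" in rec:
                meta = rec["meta"]
                continue
            if meta is None:
                raise FormatError(f"{path}: first record must carry stream metadata")
            frame = int(rec["frame"])
            for det in rec.get("detections", []):
                detections.append(_detection_from_record(frame, det, lineno))
    if meta is None:
        raise FormatError(f"{path}: no metadata record found")
    return _build_stream(meta, detections)


def _read_csv(path: Path) -> DetectionStream:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '# key=value ...' metadata line")
        meta = dict(item.split("=", 1) for item in header.lstrip("# ").split())
        reader = csv.DictReader(fh)
        detections: list[Detection] = []
        for lineno, row in enumerate(reader, start=3):
            rec = {"label": row["label"], "conf": row["confidence"],
                   "box": [row["x1"], row["y1"], row["x2"], row["y2"]]}
            detections.append(_detection_from_record(int(row["frame_index"]), rec, lineno))
    return _build_stream(meta, detections)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(track: GroundTruthTrack, path: str | Path,
                       sparse: bool = True) -> None:
    """Write a track as (frame_index, drinking) CSV; sparse keeps only positives."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "drinking"])
        for i, lab in enumerate(track.labels):
            if lab or not sparse:
                writer.writerow([i, int(lab)])


def read_ground_truth(path: str | Path, stream: DetectionStream) -> GroundTruthTrack:
    """Read frame annotations into a dense track; unlisted frames default to 0."""
    labels = np.zeros(stream.n_frames, dtype=np.uint8)
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            idx = int(row["frame_index"])
            if idx >= stream.n_frames or idx < 0:
                raise ValidationError(
                    f"frame_index {idx} outside stream of {stream.n_frames} frames"
                )
            labels[idx] = int(row["drinking"])
    return GroundTruthTrack(labels)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["pen_id", "start_s", "end_s", "duration_s", "start_clock",
                  "faucet_id", "mean_proximity", "max_proximity",
                  "start_frame", "end_frame", "fps"]


def write_events(events: Sequence[DrinkingEvent], path: str | Path) -> None:
    """Write one CSV row per event; round-trips losslessly through read_events."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_COLUMNS)
        for ev in events:
            writer.writerow([
                ev.pen_id, repr(ev.start_s), repr(ev.end_s), repr(ev.duration_s),
                "" if ev.start_clock is None else ev.start_clock.isoformat(),
                ev.faucet_id, repr(ev.mean_p), repr(ev.max_p),
                ev.start_frame, ev.end_frame, repr(ev.fps),
            ])


def read_events(path: str | Path) -> list[DrinkingEvent]:
    events: list[DrinkingEvent] = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "start_frame" not in reader.fieldnames:
            raise FormatError(f"{path}: not an events CSV")
        for row in reader:
            events.append(DrinkingEvent(
                start_frame=int(row["start_frame"]),
                end_frame=int(row["end_frame"]),
                fps=float(row["fps"]),
                faucet_id=int(row["faucet_id"]),
                start_clock=_parse_clock(row["start_clock"]) if row["start_clock"] else None,
                max_p=float(row["max_proximity"]),
                mean_p=float(row["mean_proximity"]),
                pen_id=row["pen_id"],
            ))
    return events
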