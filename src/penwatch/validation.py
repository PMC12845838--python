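"""Frame-level confusion metrics and event-level temporal concordance.

Validation compares the pipeline's output against human frame annotations in
two complementary ways: per-frame binary confusion (accuracy, precision,
recall, F1) and interval intersection-over-union of the total time each side
calls drinking.  A stride-based downsampler reproduces the reduced review
cadence used when synchronizing a human annotator with the model (every 18th
frame of 25 FPS video, an effective ~1.39 FPS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from penwatch.io import DetectionStream, GroundTruthTrack, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary frame-level confusion counts with derived rates."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            warnings.warn("no predicted positives; precision reported as 0")
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("no true positives in ground truth; recall reported as 0")
            return 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def summary(self, decimals: int = 3) -> dict[str, float]:
        return {
            "accuracy": round(self.accuracy, decimals),
            "precision": round(self.precision, decimals),
            "recall": round(self.recall, decimals),
            "f1": round(self.f1, decimals),
            "frames": self.n,
        }


@dataclass(frozen=True)
class ConcordanceResult:
    """Interval IoU of model vs annotated drinking time.

    ``model_only_s`` and ``truth_only_s`` partition the non-shared part of
    the union, so ``overlap_s + model_only_s + truth_only_s == union_s``.
    """

    overlap_s: float
    union_s: float
    model_only_s: float
    truth_only_s: float

    @property
    def iou(self) -> float:
        return 0.0 if self.union_s == 0 else self.overlap_s / self.union_s

    @property
    def model_only_frac(self) -> float:
        return 0.0 if self.union_s == 0 else self.model_only_s / self.union_s

    @property
    def truth_only_frac(self) -> float:
        return 0.0 if self.union_s == 0 else self.truth_only_s / self.union_s


def downsample(stream_or_track, stride: int):
    """Keep every ``stride``-th frame (indices divisible by ``stride``).

    For a track the labels are decimated; for a stream the surviving
    detections are re-indexed to the reduced frame grid and the fps divided
    by the stride, so downstream timing stays consistent.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if isinstance(stream_or_track, GroundTruthTrack):
        return GroundTruthTrack(stream_or_track.labels[::stride])
    if isinstance(stream_or_track, DetectionStream):
        s = stream_or_track
        kept = [replace(d, frame_index=d.frame_index // stride)
                for d in s.detections if d.frame_index % stride == 0]
        return DetectionStream(
            frame_width=s.frame_width, frame_height=s.frame_height,
            fps=s.fps / stride, session_start=s.session_start,
            n_frames=-(-s.n_frames // stride), detections=kept, pen_id=s.pen_id,
        )
    arr = np.asarray(stream_or_track)
    return arr[::stride]


def frame_confusion(pred_track, truth_track) -> ConfusionCounts:
    """Frame-by-frame confusion of two equal-length binary tracks."""
    pred = np.asarray(pred_track.labels if isinstance(pred_track, GroundTruthTrack)
                      else pred_track, dtype=bool)
    truth = np.asarray(truth_track.labels if isinstance(truth_track, GroundTruthTrack)
                       else truth_track, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"track length mismatch: {pred.size} vs {truth.size} frames"
        )
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


def _union_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    for s, e in intervals:
        if e <= s:
            raise ValidationError(f"malformed interval [{s}, {e})")
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _measure(intervals: Sequence[tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in intervals))


def _intersect(a: Sequence[tuple[float, float]],
               b: Sequence[tuple[float, float]]) -> float:
    total, i, j = 0.0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _as_intervals(events) -> list[tuple[float, float]]:
    out = []
    for ev in events:
        if hasattr(ev, "start_s"):
            out.append((float(ev.start_s), float(ev.end_s)))
        else:
            s, e = ev
            out.append((float(s), float(e)))
    return out


def temporal_concordance(pred_events, truth_events) -> ConcordanceResult:
    """Interval IoU of predicted vs annotated drinking time.

    Each side's half-open intervals are unioned first, so duplicated or
    touching events never inflate the overlap.  Accepts lists of events (with
    ``start_s``/``end_s``) or plain ``(start, end)`` pairs, in seconds.
    """
    pred = _union_intervals(_as_intervals(pred_events))
    truth = _union_intervals(_as_intervals(truth_events))
    overlap = _intersect(pred, truth)
    pred_len, truth_len = _measure(pred), _measure(truth)
    union = pred_len + truth_len - overlap
    return ConcordanceResult(
        overlap_s=overlap, union_s=union,
        model_only_s=pred_len - overlap, truth_only_s=truth_len - overlap,
    )
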