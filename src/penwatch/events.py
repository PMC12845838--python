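"""Drinking-event inference from per-frame detections.

The pipeline has four stages:

1. **Faucet localization** — faucet positions are fixed once, from the
   highest-confidence ``Water-Faucet`` detections in the first
   ``n_init_frames`` frames, and serve as the stable spatial reference for
   the whole session.
2. **Proximity scoring** — per frame, every ``Pig-Head`` centroid is scored
   against every fixed faucet centroid as ``P = 1 - d / d_diag`` where ``d``
   is the Euclidean pixel distance and ``d_diag`` the frame diagonal, so
   ``P = 1`` means coincident centroids.
3. **Frame flagging** — a frame is flagged when the best head-faucet pair
   reaches the proximity threshold (default 0.98, inclusive).
4. **Segmentation** — maximal runs of flagged frames become events; runs
   shorter than ``min_duration_s`` (default 5 s) are discarded as
   sniffing/curiosity visits that cannot reflect substantial intake.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from penwatch.io import (
    BoundingBox,
    DetectionStream,
    DrinkingEvent,
    clock_at,
)


class FaucetLocalizationError(RuntimeError):
    """No faucet could be fixed; proximity monitoring cannot start."""


@dataclass(frozen=True)
class Faucet:
    """A fixed faucet: id, box, centroid and the confidence that fixed it."""

    faucet_id: int
    box: BoundingBox
    centroid: tuple[float, float]
    confidence: float


@dataclass(frozen=True)
class FaucetMap:
    """Up to two fixed faucets, ranked by detection confidence."""

    faucets: tuple[Faucet, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.faucets) <= 2:
            raise ValueError("a faucet map holds one or two faucets")

    def __len__(self) -> int:
        return len(self.faucets)

    def __iter__(self):
        return iter(self.faucets)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([f.centroid for f in self.faucets], dtype=float)


@dataclass
class PipelineConfig:
    """Tunable parameters of the inference pipeline.

    Defaults are the deployed operating point: proximity threshold 0.98,
    5 s minimum event duration, faucets fixed from the first 30 frames,
    at most two faucets, no gap merging, and a clustering radius of 5 % of
    the frame diagonal for associating repeated faucet detections.
    """

    threshold: float = 0.98
    min_duration_s: float = 5.0
    n_init_frames: int = 30
    max_faucets: int = 2
    max_gap_frames: int = 0
    cluster_radius_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.min_duration_s < 0 or self.n_init_frames < 1:
            raise ValueError("min_duration_s >= 0 and n_init_frames >= 1 required")
        if self.max_faucets < 1 or self.max_gap_frames < 0:
            raise ValueError("max_faucets >= 1 and max_gap_frames >= 0 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def centroid(box: BoundingBox) -> tuple[float, float]:
    """Geometric center ((x1+x2)/2, (y1+y2)/2) of a box, real-valued."""
    return box.centroid


def proximity(head_centroid: Sequence[float], faucet_centroid: Sequence[float],
              d_diag: float) -> float:
    """Proximity score ``P = 1 - d / d_diag`` for one head-faucet pair."""
    if d_diag <= 0:
        raise ValueError(f"d_diag must be positive, got {d_diag}")
    d = math.dist(head_centroid, faucet_centroid)
    return 1.0 - d / d_diag


def localize_faucets(stream: DetectionStream, n_init_frames: int = 30,
                     max_faucets: int = 2,
                     cluster_radius_frac: float = 0.05) -> FaucetMap:
    """Fix faucet positions from the initial frames of the stream.

    Water-faucet detections in frames ``[0, n_init_frames)`` are greedily
    clustered: a detection joins the first cluster whose reference centroid
    lies within ``cluster_radius_frac * d_diag``, else starts a new cluster.
    Each cluster is represented by its highest-confidence detection; the
    ``max_faucets`` clusters with the highest confidence are kept, ids
    assigned in descending confidence order (0 first).
    """
    if stream.n_frames < 1:
        raise FaucetLocalizationError("stream has no frames")
    if stream.n_frames < n_init_frames:
        warnings.warn(
            f"only {stream.n_frames} frames available for faucet localization "
            f"(requested {n_init_frames})"
        )
    radius = cluster_radius_frac * stream.d_diag
    clusters: list[dict] = []  # {"ref": (x, y), "best": Detection}
    for det in stream.detections:
        if det.frame_index >= n_init_frames:
            break
        if det.label != "Water-Faucet":
            continue
        c = det.box.centroid
        for cl in clusters:
            if math.dist(c, cl["ref"]) <= radius:
                if det.confidence > cl["best"].confidence:
                    cl["best"] = det
                    cl["ref"] = c
                break
        else:
            clusters.append({"ref": c, "best": det})
    if not clusters:
        raise FaucetLocalizationError(
            f"no Water-Faucet detections in the first {n_init_frames} frames"
        )
    clusters.sort(key=lambda cl: -cl["best"].confidence)
    faucets = tuple(
        Faucet(faucet_id=i, box=cl["best"].box, centroid=cl["best"].box.centroid,
               confidence=cl["best"].confidence)
        for i, cl in enumerate(clusters[:max_faucets])
    )
    return FaucetMap(faucets)


def flag_frames(stream: DetectionStream, faucets: FaucetMap,
                threshold: float = 0.98) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame flags and per-frame, per-faucet best proximity scores.

    Returns ``(flags, p)`` where ``flags`` is a boolean array of length
    ``n_frames`` and ``p[i, j]`` is the best proximity of any pig head on
    frame ``i`` to faucet ``j`` (``-inf`` where no head was detected).
    A frame is flagged when ``max_j p[i, j] >= threshold`` — the comparison
    is inclusive so the printed constant 0.98 is itself attainable.
    """
    heads = [d for d in stream.detections if d.label == "Pig-Head"]
    p = np.full((stream.n_frames, len(faucets)), -np.inf)
    if heads:
        frames = np.array([d.frame_index for d in heads])
        cents = np.array([d.box.centroid for d in heads])
        fc = faucets.centroids
        # (n_heads, n_faucets) distances -> proximity
        dist = np.linalg.norm(cents[:, None, :] - fc[None, :, :], axis=2)
        scores = 1.0 - dist / stream.d_diag
        np.maximum.at(p, (frames[:, None], np.arange(len(faucets))[None, :]), scores)
    flags = p.max(axis=1) >= threshold
    return flags, p


def segment_events(flag_track: np.ndarray, fps: float,
                   min_duration_s: float = 5.0, max_gap_frames: int = 0,
                   p: np.ndarray | None = None,
                   session_start=None, pen_id: str = "pen") -> list[DrinkingEvent]:
    """Segment a flag track into drinking events.

    Maximal runs of flagged frames are found; runs separated by at most
    ``max_gap_frames`` unflagged frames are merged; runs shorter than
    ``min_duration_s`` are dropped.  When the per-faucet proximity matrix
    ``p`` is supplied, each event is attributed to the faucet with the
    highest mean score over the run (ties to the lower faucet id).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    flags = np.asarray(flag_track, dtype=bool)
    if flags.size == 0 or not flags.any():
        return []
    # run-length extraction on the padded diff
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    # merge runs across small gaps
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= max_gap_frames:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    events: list[DrinkingEvent] = []
    for s, e in merged:
        if (e - s) / fps < min_duration_s:
            continue
        if p is not None:
            seg = p[s:e]
            valid = np.where(np.isfinite(seg), seg, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                means = np.nanmean(valid, axis=0)
            means = np.nan_to_num(means, nan=-np.inf)
            faucet_id = int(np.argmax(means))  # argmax takes the first (lowest id) tie
            finite = seg[np.isfinite(seg)]
            max_p = float(finite.max())
            mean_p = float(finite.mean())
        else:
            faucet_id, max_p, mean_p = 0, float("nan"), float("nan")
        events.append(DrinkingEvent(
            start_frame=s, end_frame=e, fps=fps, faucet_id=faucet_id,
            start_clock=None if session_start is None else clock_at(session_start, s / fps),
            max_p=max_p, mean_p=mean_p, pen_id=pen_id,
        ))
    return events


def run_pipeline(stream: DetectionStream,
                 config: PipelineConfig | None = None) -> list[DrinkingEvent]:
    """Full inference: localize faucets, score proximity, flag, segment."""
    cfg = config or PipelineConfig()
    faucets = localize_faucets(stream, n_init_frames=cfg.n_init_frames,
                               max_faucets=cfg.max_faucets,
                               cluster_radius_frac=cfg.cluster_radius_frac)
    flags, p = flag_frames(stream, faucets, threshold=cfg.threshold)
    return segment_events(flags, stream.fps, min_duration_s=cfg.min_duration_s,
                          max_gap_frames=cfg.max_gap_frames, p=p,
                          session_start=stream.session_start, pen_id=stream.pen_id)
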