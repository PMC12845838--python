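"""Synthetic single-pen scene and detection-stream generator.

Emulates the monitoring setup end to end with no video: a fixed top-down
camera over a single-occupancy pen with one or two wall-mounted water
faucets, a pig whose head wanders the pen between faucet visits, and an
object detector that reports boxes with confidence scores and configurable
error modes (missed heads, corner jitter, spurious low-confidence boxes
drawn from the background-confusion classes).

Visit starts follow an inhomogeneous Poisson process over clock hours with
a bimodal diurnal intensity (morning and afternoon peaks within the
06:30-18:30 lights-on window); durations are lognormal.  The renderer
returns the detection stream together with the frame-exact ground-truth
track and the injected visit list, so recovery by the inference pipeline
can be checked against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time
from typing import Sequence

import numpy as np

from penwatch.io import (
    BoundingBox,
    Detection,
    DetectionStream,
    DrinkingEvent,
    GroundTruthTrack,
    clock_at,
)

#: Default hourly visit intensity (visits/hour), proportional to the observed
#: aggregate hourly event counts, scaled to 34 visits per 12 h day.
DEFAULT_HOURLY_RATE: dict[int, float] = {
    h: 34.0 * n / 612.0
    for h, n in {6: 20, 7: 25, 8: 49, 9: 51, 10: 52, 11: 41, 12: 42,
                 13: 42, 14: 69, 15: 93, 16: 82, 17: 33, 18: 13}.items()
}


@dataclass(frozen=True)
class PenScene:
    """Static scene geometry: frame, pen rectangle, faucets, head-box size."""

    frame_width: int = 1280
    frame_height: int = 720
    fps: float = 25.0
    session_start: time = time(6, 30)
    session_hours: float = 12.0
    faucet_boxes: tuple[BoundingBox, ...] = (
        BoundingBox(30.0, 280.0, 90.0, 340.0),
        BoundingBox(30.0, 420.0, 90.0, 480.0),
    )
    head_size_px: float = 70.0
    pen_margin_px: float = 60.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.faucet_boxes) <= 2:
            raise ValueError("scene needs one or two faucets")
        for box in self.faucet_boxes:
            if not box.within(self.frame_width, self.frame_height):
                raise ValueError("faucet box outside frame")

    @property
    def d_diag(self) -> float:
        return float(np.hypot(self.frame_width, self.frame_height))

    @property
    def n_frames(self) -> int:
        return int(round(self.session_hours * 3600.0 * self.fps))

    @property
    def faucet_centroids(self) -> np.ndarray:
        return np.array([b.centroid for b in self.faucet_boxes])


@dataclass(frozen=True)
class ScheduleParams:
    """Generating process for the daily visit schedule.

    ``hourly_rate`` maps clock hour to expected visits/hour; the default is
    bimodal with morning (08-10) and afternoon (14-16) peaks.  Durations are
    lognormal (median ``exp(duration_mu)`` seconds) with a hard floor so
    every scheduled visit is long enough to register as an event.
    """

    hourly_rate: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HOURLY_RATE))
    duration_mu: float = np.log(30.0)
    duration_sigma: float = 0.8
    duration_floor_s: float = 6.0
    min_gap_s: float = 5.0
    confine_to_hour: bool = False


@dataclass(frozen=True)
class NoiseModel:
    """Detector error model; the all-zero default is the noise-free reference."""

    head_miss_prob: float = 0.0
    jitter_std_px: float = 0.0
    spurious_rate: float = 0.0
    faucet_miss_prob: float = 0.0
    head_conf_beta: tuple[float, float] = (20.0, 2.0)
    faucet_conf_beta: tuple[float, float] = (20.0, 2.0)
    spurious_conf_beta: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        for p in (self.head_miss_prob, self.faucet_miss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("noise probabilities must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")


@dataclass(frozen=True)
class Visit:
    """One scheduled faucet visit (seconds relative to session start)."""

    start_s: float
    duration_s: float
    faucet_id: int

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def sample_schedule(params: ScheduleParams, scene: PenScene,
                    seed: int | np.random.Generator = 0) -> list[Visit]:
    """Draw a non-overlapping visit schedule from the hourly intensity.

    Candidate starts are an inhomogeneous Poisson process (per-clock-hour
    counts, uniform placement within the hour); overlapping candidates are
    thinned in start order, keeping the earlier visit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start_clock_s = (scene.session_start.hour * 3600
                     + scene.session_start.minute * 60 + scene.session_start.second)
    session_len = scene.session_hours * 3600.0
    candidates: list[tuple[float, float, int]] = []
    for hour, rate in sorted(params.hourly_rate.items()):
        if rate <= 0:
            continue
        # overlap of this clock hour with the session window, in session seconds
        lo = max(hour * 3600.0 - start_clock_s, 0.0)
        hi = min((hour + 1) * 3600.0 - start_clock_s, session_len)
        if hi <= lo:
            continue
        n = rng.poisson(rate * (hi - lo) / 3600.0)
        starts = rng.uniform(lo, hi, size=n)
        durs = np.maximum(
            rng.lognormal(params.duration_mu, params.duration_sigma, size=n),
            params.duration_floor_s,
        )
        faucet = rng.integers(0, len(scene.faucet_boxes), size=n)
        if params.confine_to_hour:
            durs = np.minimum(durs, hi - starts)
        candidates += [(float(s), float(d), int(f))
                       for s, d, f in zip(starts, durs, faucet)
                       if d >= params.duration_floor_s and s + d <= session_len]
    candidates.sort()
    visits: list[Visit] = []
    for s, d, f in candidates:
        if visits and s < visits[-1].end_s + params.min_gap_s:
            continue
        visits.append(Visit(start_s=s, duration_s=d, faucet_id=f))
    return visits


def _reflected_walk(n: int, lo: np.ndarray, hi: np.ndarray, step: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Bounded random walk in a rectangle via modular reflection."""
    span = hi - lo
    steps = rng.normal(0.0, step, size=(n, 2))
    steps[0] = rng.uniform(lo, hi)
    raw = np.cumsum(steps, axis=0)
    folded = np.abs((raw - lo) % (2 * span) - span)
    return lo + span - folded  # stays in [lo, hi]


def render_stream(scene: PenScene, schedule: Sequence[Visit],
                  noise: NoiseModel = NoiseModel(),
                  seed: int | np.random.Generator = 0,
                  pen_id: str = "sim-pen",
                  ) -> tuple[DetectionStream, GroundTruthTrack, list[DrinkingEvent]]:
    """Render a schedule into a detection stream with ground truth.

    During a visit the head centroid sits within 1 % of the frame diagonal
    of the assigned faucet centroid (proximity >= 0.99 before jitter);
    between visits a bounded random walk keeps the centroid more than 3 %
    of the diagonal away from every faucet (proximity < 0.97).  Faucet
    detections are emitted over the first 30 frames so localization can fix
    the reference positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scene.n_frames
    fps = scene.fps
    half = scene.head_size_px / 2.0
    d_diag = scene.d_diag

    truth = np.zeros(n, dtype=np.uint8)
    visit_faucet = np.full(n, -1, dtype=int)
    true_events: list[DrinkingEvent] = []
    for v in schedule:
        s, e = int(round(v.start_s * fps)), int(round(v.end_s * fps))
        if s < 0 or e > n:
            raise ValueError(f"visit [{v.start_s}, {v.end_s}) s outside the session")
        if e <= s:
            continue
        truth[s:e] = 1
        visit_faucet[s:e] = v.faucet_id
        true_events.append(DrinkingEvent(
            start_frame=s, end_frame=e, fps=fps, faucet_id=v.faucet_id,
            start_clock=clock_at(scene.session_start, s / fps), pen_id=pen_id))

    margin = scene.pen_margin_px + half
    lo = np.array([margin, margin])
    hi = np.array([scene.frame_width - margin, scene.frame_height - margin])
    pos = _reflected_walk(n, lo, hi, 0.02 * d_diag, rng)

    # keep the wandering head out of the proximity-trigger zone; the push
    # direction is mirrored into the pen (x >= faucet x) so boxes stay in frame
    fc = scene.faucet_centroids
    keep_out = 0.03 * d_diag
    for j in range(len(fc)):
        delta = pos - fc[j]
        dist = np.linalg.norm(delta, axis=1)
        close = (dist < keep_out) & (truth == 0)
        if close.any():
            safe = np.where(dist[close, None] > 0, delta[close], np.array([1.0, 0.0]))
            safe[:, 0] = np.abs(safe[:, 0])
            norm = np.linalg.norm(safe, axis=1, keepdims=True)
            pos[close] = fc[j] + safe / norm * keep_out * 1.01

    # pin visit frames to the assigned faucet with sub-1 % jitter
    in_visit = truth == 1
    if in_visit.any():
        offsets = rng.normal(0.0, 0.002 * d_diag, size=(int(in_visit.sum()), 2))
        r = np.linalg.norm(offsets, axis=1, keepdims=True)
        cap = 0.01 * d_diag
        offsets = np.where(r > cap, offsets * cap / r, offsets)
        pos[in_visit] = fc[visit_faucet[in_visit]] + offsets

    detections: list[Detection] = []
    n_init = min(30, n)
    for j, fbox in enumerate(scene.faucet_boxes):
        emit = rng.random(n_init) >= noise.faucet_miss_prob
        confs = rng.beta(*noise.faucet_conf_beta, size=n_init)
        for i in np.flatnonzero(emit):
            detections.append(Detection(int(i), "Water-Faucet", float(confs[i]), fbox))

    head_emit = rng.random(n) >= noise.head_miss_prob
    head_conf = rng.beta(*noise.head_conf_beta, size=n)
    jitter = (rng.normal(0.0, noise.jitter_std_px, size=(n, 4))
              if noise.jitter_std_px > 0 else np.zeros((n, 4)))
    x1 = np.maximum(pos[:, 0] - half + jitter[:, 0], 0.0)
    y1 = np.maximum(pos[:, 1] - half + jitter[:, 1], 0.0)
    x2 = np.maximum(pos[:, 0] + half + jitter[:, 2], x1 + 1.0)
    y2 = np.maximum(pos[:, 1] + half + jitter[:, 3], y1 + 1.0)
    posture_conf = rng.beta(*noise.head_conf_beta, size=n)
    for i in np.flatnonzero(head_emit):
        box = BoundingBox(float(x1[i]), float(y1[i]), float(x2[i]), float(y2[i]))
        detections.append(Detection(int(i), "Pig-Head", float(head_conf[i]), box))
        # posture placeholder: body box inflated around the head
        bx1, by1 = max(x1[i] - half, 0.0), max(y1[i] - half, 0.0)
        body = BoundingBox(bx1, by1,
                           min(x2[i] + half, float(scene.frame_width)),
                           min(y2[i] + half, float(scene.frame_height)))
        detections.append(Detection(int(i), "Pig-Standing", float(posture_conf[i]), body))

    if noise.spurious_rate > 0:
        counts = rng.poisson(noise.spurious_rate, size=n)
        for i in np.flatnonzero(counts):
            for _ in range(int(counts[i])):
                label = "Feces" if rng.random() < 0.5 else "Pig-Head"
                cx = rng.uniform(half, scene.frame_width - half)
                cy = rng.uniform(half, scene.frame_height - half)
                box = BoundingBox(cx - half, cy - half, cx + half, cy + half)
                conf = float(rng.beta(*noise.spurious_conf_beta))
                detections.append(Detection(int(i), label, conf, box))

    detections.sort(key=lambda d: d.frame_index)
    stream = DetectionStream(
        frame_width=scene.frame_width, frame_height=scene.frame_height,
        fps=fps, session_start=scene.session_start, n_frames=n,
        detections=detections, pen_id=pen_id,
    )
    return stream, GroundTruthTrack(truth), true_events


def simulate_session(seed: int = 0, scene: PenScene | None = None,
                     params: ScheduleParams | None = None,
                     noise: NoiseModel = NoiseModel(),
                     ) -> tuple[DetectionStream, GroundTruthTrack, list[DrinkingEvent]]:
    """Sample a schedule and render it in one call (single shared rng)."""
    rng = np.random.default_rng(seed)
    scene = scene or PenScene()
    schedule = sample_schedule(params or ScheduleParams(), scene, rng)
    return render_stream(scene, schedule, noise, rng)
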