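from datetime import time

import numpy as np
import pytest

from penwatch.io import BoundingBox, Detection, DetectionStream
from penwatch.simulate import PenScene, ScheduleParams, simulate_session


@pytest.fixture(scope="session")
def small_scene() -> PenScene:
    """Two-hour, 5 FPS morning session — fast but long enough for visits."""
    return PenScene(fps=5.0, session_hours=2.0)


@pytest.fixture(scope="session")
def zero_noise_session(small_scene):
    """(stream, truth, true_events) with the noise-free detector."""
    return simulate_session(seed=11, scene=small_scene, params=ScheduleParams())


def make_stream(detections, n_frames=100, width=640, height=480, fps=25.0):
    return DetectionStream(
        frame_width=width, frame_height=height, fps=fps,
        session_start=time(6, 30), n_frames=n_frames,
        detections=list(detections),
    )


def det(frame, label, conf, x1, y1, x2, y2):
    return Detection(frame, label, conf, BoundingBox(x1, y1, x2, y2))


@pytest.fixture
def faucet_stream():
    """One faucet seen in all of the first 30 frames, confidence peaking at frame 7."""
    dets = [det(i, "Water-Faucet", 0.93 if i == 7 else 0.6 + 0.001 * i,
                100, 100, 140, 140) for i in range(30)]
    return make_stream(dets, n_frames=200)
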