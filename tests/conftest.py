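"""Shared fixtures: random trajectory factories and small hand instances."""

from __future__ import annotations

import numpy as np
import pytest

from spermeval.trackio import Detection, Track, TrackSet


def make_random_trackset(
    rng: np.random.Generator,
    n_tracks: int,
    n_frames: int,
    field: float = 200.0,
    step: float = 4.0,
    gap_prob: float = 0.1,
) -> TrackSet:
    """Random-walk tracks with random start frames and occasional gaps."""
    dets = []
    for i in range(n_tracks):
        start = int(rng.integers(0, max(1, n_frames // 3)))
        pos = rng.uniform(0, field, size=2)
        for f in range(start, n_frames):
            if f > start and rng.random() < gap_prob:
                continue
            pos = pos + rng.normal(0, step, size=2)
            dets.append(Detection(frame=f, x=float(pos[0]), y=float(pos[1]), label=f"t{i}"))
    return TrackSet.from_detections(dets)


def straight_track(
    label: str = "s",
    n: int = 10,
    start=(0.0, 0.0),
    step=(1.0, 0.0),
    start_frame: int = 0,
) -> Track:
    dets = tuple(
        Detection(
            frame=start_frame + i,
            x=start[0] + i * step[0],
            y=start[1] + i * step[1],
            label=label,
        )
        for i in range(n)
    )
    return Track(label=label, detections=dets)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_trackset(rng):
    return make_random_trackset(rng, n_tracks=6, n_frames=30)
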