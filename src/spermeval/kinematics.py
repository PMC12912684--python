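"""Motion filtering, CASA kinematic parameters and distribution comparison.

The three standard computer-aided semen analysis (CASA) velocities are
computed per track as whole-track time averages, in microns per second:

* **VCL** (curvilinear velocity) — total path length along the recorded
  trajectory divided by elapsed time.
* **VSL** (straight-line velocity) — chord length from first to last
  detection divided by elapsed time.
* **VAP** (average path velocity) — VCL of a smoothed path (centered
  moving average over recorded detections).

Elapsed time is (last_frame - first_frame) / fps, so tracks with internal
gaps are not penalized twice; path distances are taken between consecutive
recorded detections with no interpolation across gaps.

The module also provides the span-radius motion filter used to exclude
immotile cells and debris before evaluation, shared-bin velocity
histograms, and the first Wasserstein (Earth Mover's) distance between
empirical velocity distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import wasserstein_distance

from .errors import UndefinedKinematicError
from .trackio import Track, TrackSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KinematicConfig:
    """Calibration from pixels/frames to microns/seconds.

    ``window`` is the smoothing window (frames, odd, >= 1) used by the
    averaged path underlying VAP; window 1 makes VAP identical to VCL.
    """

    um_per_px: float
    fps: float
    window: int = 5

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 1, got {self.window}")


@dataclass(frozen=True)
class FilterConfig:
    """Motion/length filter: keep tracks with span_radius > epsilon (strict)
    and at least min_length recorded detections."""

    epsilon: float = 5.0
    min_length: int = 9

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1, got {self.min_length}")


@dataclass(frozen=True)
class KinematicsRecord:
    """Per-track kinematics with calibration provenance."""

    label: str
    vcl: float
    vsl: float
    vap: float
    n_detections: int
    duration: float  # seconds
    config: KinematicConfig

    def __post_init__(self):
        tol = 1e-9 * max(1.0, self.vcl)
        if self.vsl > self.vcl + tol or self.vap > self.vcl + tol:
            raise ValueError(
                f"track {self.label!r}: VSL/VAP exceed VCL "
                f"({self.vsl}, {self.vap} vs {self.vcl})"
            )


def filter_tracks(ts: TrackSet, fc: FilterConfig) -> TrackSet:
    """Remove trajectories that do not spatially extend past radius epsilon
    or are shorter than min_length detections. Applied identically to
    reference and prediction sets."""
    kept = tuple(
        t
        for t in ts
        if t.span_radius > fc.epsilon and len(t) >= fc.min_length
    )
    return TrackSet(tracks=kept)


def _duration_s(track: Track, kc: KinematicConfig) -> float:
    if len(track) < 2:
        raise UndefinedKinematicError(
            f"track {track.label!r}: velocity undefined for a single detection"
        )
    return (track.frames[-1] - track.frames[0]) / kc.fps


def vcl(track: Track, kc: KinematicConfig) -> float:
    """Curvilinear velocity, um/s."""
    dt = _duration_s(track, kc)
    xy = track.coordinates
    path = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    return path * kc.um_per_px / dt


def vsl(track: Track, kc: KinematicConfig) -> float:
    """Straight-line velocity, um/s."""
    dt = _duration_s(track, kc)
    xy = track.coordinates
    chord = float(np.linalg.norm(xy[-1] - xy[0]))
    return chord * kc.um_per_px / dt


def smooth_path(track: Track, window: int) -> np.ndarray:
    """Centered moving average over recorded detections.

    The window shrinks symmetrically near the ends (the i-th output point
    averages inputs i-k .. i+k with k = min(half, i, n-1-i)), so the output
    has the same number of points, the same frame stamps, and identical
    endpoints; window 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    xy = track.coordinates
    n = len(xy)
    half = (window - 1) // 2
    out = np.empty_like(xy)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = xy[i - k : i + k + 1].mean(axis=0)
    return out


def vap(track: Track, kc: KinematicConfig) -> float:
    """Average path velocity, um/s: VCL applied to the smoothed path."""
    dt = _duration_s(track, kc)
    sm = smooth_path(track, kc.window)
    path = float(np.sum(np.linalg.norm(np.diff(sm, axis=0), axis=1)))
    return path * kc.um_per_px / dt


def velocity_histogram(
    samples: Mapping[str, Sequence[float]], n_bins: int = 20
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Histogram per-track velocities on bins shared across algorithms.

    Bins are ``n_bins`` equally spaced intervals between 0 and the maximum
    velocity observed among all algorithms, so distributions are directly
    comparable. Returns (edges, {algorithm: counts}).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    total = sum(a.size for a in arrays.values())
    if total == 0:
        raise ValueError("velocity_histogram needs at least one value")
    vmax = max((a.max() for a in arrays.values() if a.size), default=0.0)
    if vmax <= 0:
        vmax = 1.0  # degenerate all-zero input: any positive span works
    edges = np.linspace(0.0, vmax, n_bins + 1)
    # right-closed bins (0 kept in the first) so the shared maximum and any
    # value sitting exactly on an edge land in the bin below it
    counts = {}
    for k, a in arrays.items():
        idx = np.clip(np.searchsorted(edges, a, side="left") - 1, 0, n_bins - 1)
        counts[k] = np.bincount(idx[(a >= 0) & (a <= vmax)], minlength=n_bins)
    return edges, counts


def emd(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """First Wasserstein (Earth Mover's) distance between two velocity samples.

    For equal sample sizes this equals the mean absolute difference of the
    sorted samples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("emd requires two non-empty samples")
    return float(wasserstein_distance(a, b))


def kinematics_table(
    ts: TrackSet, kc: KinematicConfig, fc: FilterConfig | None = None
) -> list[KinematicsRecord]:
    """One kinematics record per retained track with >= 2 detections."""
    if fc is not None:
        ts = filter_tracks(ts, fc)
    records = []
    skipped = 0
    for t in ts:
        if len(t) < 2:
            skipped += 1
            continue
        records.append(
            KinematicsRecord(
                label=t.label,
                vcl=vcl(t, kc),
                vsl=vsl(t, kc),
                vap=vap(t, kc),
                n_detections=len(t),
                duration=_duration_s(t, kc),
                config=kc,
            )
        )
    if skipped:
        logger.info("kinematics_table: skipped %d single-detection track(s)", skipped)
    return records


def subset_window(ts: TrackSet, start_frame: int, n_frames: int) -> TrackSet:
    """Clip every track to frames [start_frame, start_frame + n_frames).

    Emulates short-timescale CASA analysis (e.g. 2 s at 9 fps = 18 frames).
    Tracks left with fewer than 2 detections are dropped.
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    lo, hi = start_frame, start_frame + n_frames
    kept = []
    for t in ts:
        dets = tuple(d for d in t.detections if lo <= d.frame < hi)
        if len(dets) >= 2:
            kept.append(Track(label=t.label, detections=dets))
    return TrackSet(tracks=tuple(kept))
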