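"""Baseline centroid detector, bounding-box correction, and frame linker.

The detector follows the classic Crocker–Grier particle-localization
scheme: a spatial band-pass (Gaussian noise smoothing minus boxcar
background at the feature-diameter scale), grey-dilation local maxima with
a minimum separation of one diameter, sub-pixel centroid refinement inside
a circular mask, and rejection of features whose integrated brightness
(mass) falls below ``minmass``. Defaults are an 11 px diameter and 500
minmass. Exact numeric agreement with any external implementation is a
non-goal; only the localization contracts tested here are promised.

The linker performs per-frame-transition globally optimal one-to-one
assignment (Hungarian) between active tracks — predicted at their last
known position — and new detections, minimizing total squared displacement
among pairs within ``search_range``; lost tracks survive up to ``memory``
skipped frames and are resurrected without interpolated detections.
Defaults are a 25 px search range and 3-frame memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .trackio import BBoxAnnotation, Detection, TrackSet


@dataclass(frozen=True)
class DetectConfig:
    diameter: int = 11  # feature size, odd px
    minmass: float = 500.0  # minimum integrated brightness
    invert: bool = False  # dark features on bright background
    noise_sigma: float = 1.0  # Gaussian noise-smoothing scale, px

    def __post_init__(self):
        if self.diameter < 3 or self.diameter % 2 == 0:
            raise ValueError(f"diameter must be odd >= 3, got {self.diameter}")
        if self.minmass < 0:
            raise ValueError(f"minmass must be >= 0, got {self.minmass}")


@dataclass(frozen=True)
class LinkConfig:
    search_range: float = 25.0  # max per-frame displacement, px
    memory: int = 3  # frames a lost particle may skip

    def __post_init__(self):
        if self.search_range <= 0:
            raise ValueError(f"search_range must be > 0, got {self.search_range}")
        if self.memory < 0:
            raise ValueError(f"memory must be >= 0, got {self.memory}")


def bandpass(image: np.ndarray, diameter: int, noise_sigma: float = 1.0) -> np.ndarray:
    """Spatial band-pass: Gaussian smoothing minus boxcar background.

    Suppresses pixel noise below ``noise_sigma`` and background structure
    above the feature scale; negative values are clipped to zero.
    """
    img = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, noise_sigma, mode="nearest")
    background = ndimage.uniform_filter(img, diameter, mode="nearest")
    return np.clip(smoothed - background, 0.0, None)


def _circular_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2) <= radius**2


def detect_frame(image: np.ndarray, dc: DetectConfig = DetectConfig()) -> pd.DataFrame:
    """Locate bright spots in one grayscale frame.

    Returns a DataFrame with columns ``x`` (column), ``y`` (row) and
    ``mass`` (integrated band-passed brightness), one row per accepted
    feature, sorted by (y, x).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    if min(img.shape) < dc.diameter:
        raise ValueError(
            f"image {img.shape} smaller than feature diameter {dc.diameter}"
        )
    if dc.invert:
        img = img.max() - img
    bp = bandpass(img, dc.diameter, dc.noise_sigma)

    dilated = ndimage.grey_dilation(bp, size=dc.diameter, mode="constant")
    maxima = (bp == dilated) & (bp > 0)
    if dc.minmass > 0:
        # cheap vectorized pre-filter: the boxcar sum over the diameter window
        # upper-bounds the circular-mask mass, so candidates falling below half
        # of minmass can never survive; this keeps noise maxima out of the
        # (Python-level) refinement loop
        local_sum = ndimage.uniform_filter(bp, dc.diameter, mode="constant") * dc.diameter**2
        maxima &= local_sum >= 0.5 * dc.minmass
    radius = dc.diameter // 2
    # exclude maxima whose refinement mask would leave the image
    maxima[:radius, :] = maxima[-radius:, :] = False
    maxima[:, :radius] = maxima[:, -radius:] = False
    peaks = np.argwhere(maxima)
    if peaks.size == 0:
        return pd.DataFrame(columns=["x", "y", "mass"])

    # greedy suppression of peaks closer than one diameter, brightest first
    order = np.argsort(-bp[peaks[:, 0], peaks[:, 1]], kind="stable")
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= dc.diameter for q in kept):
            kept.append(p)

    mask = _circular_mask(radius)
    my, mx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    rows = []
    h, w = bp.shape
    for p in kept:
        cy, cx = int(p[0]), int(p[1])
        off_x = off_y = 0.0
        mass = 0.0
        # iterative sub-pixel refinement: recentre the mask on the centroid
        for _ in range(10):
            win = bp[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1]
            m = win * mask
            mass = m.sum()
            if mass <= 0:
                break
            off_y = (m * my).sum() / mass
            off_x = (m * mx).sum() / mass
            if abs(off_y) > 0.6 or abs(off_x) > 0.6:
                ny = min(max(cy + int(round(off_y)), radius), h - radius - 1)
                nx = min(max(cx + int(round(off_x)), radius), w - radius - 1)
                if (ny, nx) == (cy, cx):
                    break
                cy, cx = ny, nx
            else:
                break
        if mass >= dc.minmass:
            rows.append((cx + off_x, cy + off_y, float(mass)))
    df = pd.DataFrame(rows, columns=["x", "y", "mass"])
    return df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)


def detect_stack(
    images: Mapping[int, np.ndarray], dc: DetectConfig = DetectConfig()
) -> dict[int, pd.DataFrame]:
    """Run :func:`detect_frame` over a frame-indexed image mapping."""
    return {f: detect_frame(images[f], dc) for f in sorted(images)}


def correct_bboxes(
    detections: Mapping[int, pd.DataFrame | np.ndarray],
    boxes: Sequence[BBoxAnnotation],
) -> pd.DataFrame:
    """Replace each bounding-box center with the interior detection, when unique.

    For every box, detections of the same frame lying inside the box are
    collected; if exactly one is present its coordinates are used,
    otherwise (zero or multiple, i.e. ambiguous) the box center is kept.
    Returns a DataFrame with columns ``frame, label, x, y, from_detection``
    where ``label`` is the box's index within its frame.
    """
    pts_by_frame: dict[int, np.ndarray] = {}
    for f, d in detections.items():
        arr = d[["x", "y"]].to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d)
        pts_by_frame[f] = arr.reshape(-1, 2)
    rows = []
    index_in_frame: dict[int, int] = {}
    for box in boxes:
        i = index_in_frame.get(box.frame, 0)
        index_in_frame[box.frame] = i + 1
        pts = pts_by_frame.get(box.frame, np.empty((0, 2)))
        inside = pts[
            (np.abs(pts[:, 0] - box.cx) <= box.w / 2)
            & (np.abs(pts[:, 1] - box.cy) <= box.h / 2)
        ]
        if len(inside) == 1:
            x, y, used = float(inside[0, 0]), float(inside[0, 1]), True
        else:
            x, y, used = box.cx, box.cy, False
        rows.append((box.frame, str(i), x, y, used))
    return pd.DataFrame(rows, columns=["frame", "label", "x", "y", "from_detection"])


def link(
    detections: Mapping[int, pd.DataFrame | np.ndarray],
    lc: LinkConfig = LinkConfig(),
) -> TrackSet:
    """Link per-frame detections into trajectories.

    Per frame transition a globally optimal one-to-one assignment connects
    active tracks to new detections (squared-displacement cost, pairs
    beyond ``search_range`` forbidden). Unmatched detections start new
    labels, issued in order of first appearance; unmatched tracks stay
    resurrectable for ``memory`` skipped frames. Gaps remain in the output
    (no interpolation).
    """
    frames = sorted(detections)
    next_label = 0
    # each live track: [label:int, first_frame, last_frame, last_xy, dets:list]
    live: list[list] = []
    finished: list[list] = []

    for f in frames:
        d = detections[f]
        pts = (
            d[["x", "y"]].to_numpy()
            if isinstance(d, pd.DataFrame)
            else np.asarray(d, dtype=float).reshape(-1, 2)
        )
        # deterministic within-frame order
        if len(pts):
            order = np.lexsort((pts[:, 0], pts[:, 1]))
            pts = pts[order]

        still, expired = [], []
        for t in live:
            (still if f - t[2] <= lc.memory + 1 else expired).append(t)
        finished.extend(expired)
        # seniority (older first_frame first, then lower label) fixes
        # tie-breaking among equal-cost assignments via solver ordering
        still.sort(key=lambda t: (t[1], t[0]))
        live = still

        assigned_tracks: set[int] = set()
        assigned_pts: set[int] = set()
        if live and len(pts):
            last = np.array([t[3] for t in live])
            disp = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            feasible = disp <= lc.search_range
            cost2 = disp**2
            big = cost2[feasible].sum() + lc.search_range**2 + 1.0 if feasible.any() else 1.0
            rows, cols = linear_sum_assignment(np.where(feasible, cost2, big))
            for r, c in zip(rows, cols):
                if feasible[r, c]:
                    t = live[r]
                    t[2] = f
                    t[3] = pts[c]
                    t[4].append((f, pts[c][0], pts[c][1]))
                    assigned_tracks.add(r)
                    assigned_pts.add(c)
        for c in range(len(pts)):
            if c not in assigned_pts:
                live.append(
                    [next_label, f, f, pts[c], [(f, pts[c][0], pts[c][1])]]
                )
                next_label += 1

    finished.extend(live)
    finished.sort(key=lambda t: t[0])
    dets = [
        Detection(frame=fr, x=float(x), y=float(y), label=str(t[0]))
        for t in finished
        for fr, x, y in t[4]
    ]
    return TrackSet.from_detections(dets)
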