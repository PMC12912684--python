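"""Per-frame one-to-one association of ground-truth and predicted centroids.

Sperm are represented as single head-centroid points rather than masks or
boxes, so the pairing between prediction and reference is computed per
frame by the Hungarian algorithm on Euclidean centroid distance, with a
hard distance cutoff tau. The objective is cardinality-first: among
assignments using only pairs with distance <= tau, the number of matches
is maximized, and among those the total matched distance is minimized.
Leftover ground-truth detections are false negatives, leftover predicted
detections false positives. The resulting :class:`MatchTable` is the single
source of truth consumed by every tracking metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .trackio import Detection, TrackSet

#: default association cutoff, px — mirrors the baseline linker search range
DEFAULT_CUTOFF = 25.0


@dataclass(frozen=True)
class FrameMatch:
    """Association result for a single frame."""

    matches: tuple[tuple[Detection, Detection, float], ...]  # (gt, pred, distance)
    fn: tuple[Detection, ...]  # unmatched ground truth
    fp: tuple[Detection, ...]  # unmatched predictions


@dataclass(frozen=True)
class MatchTable:
    """Per-frame one-to-one GT<->prediction correspondences with distances."""

    frames: dict[int, FrameMatch]
    cutoff: float

    @property
    def tp(self) -> int:
        return sum(len(fm.matches) for fm in self.frames.values())

    @property
    def fn(self) -> int:
        return sum(len(fm.fn) for fm in self.frames.values())

    @property
    def fp(self) -> int:
        return sum(len(fm.fp) for fm in self.frames.values())

    @cached_property
    def gt_to_pred(self) -> dict[tuple[int, str], str]:
        """(frame, gt_label) -> pred_label for every match."""
        return {
            (f, g.label): p.label
            for f, fm in self.frames.items()
            for g, p, _ in fm.matches
        }

    @cached_property
    def pred_to_gt(self) -> dict[tuple[int, str], str]:
        """(frame, pred_label) -> gt_label for every match."""
        return {
            (f, p.label): g.label
            for f, fm in self.frames.items()
            for g, p, _ in fm.matches
        }


def match_frame(
    gt: Sequence[Detection], pred: Sequence[Detection], cutoff: float
) -> FrameMatch:
    """Match one frame's detections one-to-one under a distance cutoff.

    Maximum-cardinality matching among pairs with distance <= cutoff
    (inclusive); among maximum-cardinality matchings the total distance is
    minimal. Implemented as a Hungarian solve with a large finite penalty M
    for forbidden pairs, M > (n + m) * cutoff, so every feasible match is
    preferred over leaving a pair unmatched; penalized assignments are
    discarded afterwards.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    gt = sorted(gt, key=lambda d: d.label)
    pred = sorted(pred, key=lambda d: d.label)
    if not gt or not pred:
        return FrameMatch(matches=(), fn=tuple(gt), fp=tuple(pred))

    gxy = np.array([[d.x, d.y] for d in gt])
    pxy = np.array([[d.x, d.y] for d in pred])
    dist = cdist(gxy, pxy)
    feasible = dist <= cutoff
    big = (len(gt) + len(pred) + 1) * cutoff
    cost = np.where(feasible, dist, big)

    rows, cols = linear_sum_assignment(cost)
    matches, used_g, used_p = [], set(), set()
    for r, c in zip(rows, cols):
        if feasible[r, c]:
            matches.append((gt[r], pred[c], float(dist[r, c])))
            used_g.add(r)
            used_p.add(c)
    fn = tuple(d for i, d in enumerate(gt) if i not in used_g)
    fp = tuple(d for i, d in enumerate(pred) if i not in used_p)
    return FrameMatch(matches=tuple(matches), fn=fn, fp=fp)


def build_match_table(gt: TrackSet, pred: TrackSet, cutoff: float) -> MatchTable:
    """Apply :func:`match_frame` to every frame of the combined frame range."""
    gt_by_frame = gt.detections_by_frame()
    pred_by_frame = pred.detections_by_frame()
    ranges = [r for r in (gt.frame_range, pred.frame_range) if r is not None]
    frames: dict[int, FrameMatch] = {}
    if ranges:
        lo = min(r[0] for r in ranges)
        hi = max(r[1] for r in ranges)
        for f in range(lo, hi + 1):
            frames[f] = match_frame(
                gt_by_frame.get(f, ()), pred_by_frame.get(f, ()), cutoff
            )
    return MatchTable(frames=frames, cutoff=cutoff)
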