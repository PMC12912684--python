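"""Trajectory domain types and I/O.

The interchange format is a plain CSV holding one detection per row with
columns ``x``, ``y``, ``label`` and ``frame``. On read, column names are
matched case-insensitively and in any order; on write, the header is fixed
to ``x,y,label,frame``. Coordinates are pixels in image convention (origin
top-left, y increasing downward); frames are non-negative integers; labels
are opaque strings ("1" and "01" are distinct). Physical units (microns,
seconds) enter only through :class:`spermeval.kinematics.KinematicConfig`.

Bounding-box annotations follow the YOLO per-frame layout: one text file
per frame, each row ``class cx cy w h`` in coordinates normalized to [0, 1].
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TrackFormatError, TrackValidationError

logger = logging.getLogger(__name__)

#: canonical column names of the trajectory CSV dialect
CANONICAL_COLUMNS = ("x", "y", "label", "frame")


@dataclass(frozen=True)
class Detection:
    """One localized sperm centroid: position of a labelled object in a frame."""

    frame: int
    x: float
    y: float
    label: str

    def __post_init__(self):
        if self.frame < 0:
            raise TrackValidationError(f"frame must be >= 0, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise TrackValidationError(
                f"non-finite coordinates ({self.x}, {self.y}) for label "
                f"{self.label!r} at frame {self.frame}"
            )

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Track:
    """A single trajectory: time-ordered detections sharing one label.

    Frame indices are strictly increasing; gaps are legal (a linker with
    frame memory produces them) and are never interpolated here.
    """

    label: str
    detections: tuple[Detection, ...]

    def __post_init__(self):
        if len(self.detections) == 0:
            raise TrackValidationError(f"track {self.label!r} has no detections")
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise TrackValidationError(
                f"track {self.label!r}: frame indices must strictly increase, got {frames}"
            )
        for d in self.detections:
            if d.label != self.label:
                raise TrackValidationError(
                    f"detection labelled {d.label!r} inside track {self.label!r}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of x, y positions in recorded order."""
        return np.array([[d.x, d.y] for d in self.detections], dtype=float)

    @property
    def span_radius(self) -> float:
        """Maximum Euclidean distance of any detection from the first one, px.

        This is the spatial extent tested against the motion-filter radius
        epsilon: immotile cells and debris jitter inside a small span while
        swimming sperm move well beyond it.
        """
        xy = self.coordinates
        return float(np.max(np.linalg.norm(xy - xy[0], axis=1)))

    def edges(self) -> list[tuple[int, int]]:
        """Frame pairs of temporally consecutive recorded detections.

        Gap-spanning pairs count as one edge: a track recorded at frames
        (3, 4, 7) has edges (3, 4) and (4, 7).
        """
        f = self.frames
        return list(zip(f, f[1:]))


@dataclass(frozen=True)
class TrackSet:
    """All trajectories of one video (ground truth or prediction)."""

    tracks: tuple[Track, ...]

    def __post_init__(self):
        labels = [t.label for t in self.tracks]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TrackValidationError(f"duplicate track labels: {dupes}")

    @classmethod
    def from_detections(cls, detections: Iterable[Detection]) -> "TrackSet":
        """Group detections by label into tracks, sorting each by frame."""
        by_label: dict[str, list[Detection]] = {}
        for d in detections:
            by_label.setdefault(d.label, []).append(d)
        tracks = []
        for label, dets in by_label.items():
            dets.sort(key=lambda d: d.frame)
            frames = [d.frame for d in dets]
            if len(set(frames)) != len(frames):
                dupes = sorted({f for f in frames if frames.count(f) > 1})
                raise TrackValidationError(
                    f"label {label!r} has multiple detections at frame(s) {dupes}"
                )
            tracks.append(Track(label=label, detections=tuple(dets)))
        tracks.sort(key=lambda t: t.label)
        return cls(tracks=tuple(tracks))

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.tracks]

    @property
    def by_label(self) -> dict[str, Track]:
        return {t.label: t for t in self.tracks}

    @property
    def n_detections(self) -> int:
        return sum(len(t) for t in self.tracks)

    @property
    def frame_range(self) -> tuple[int, int] | None:
        """(min_frame, max_frame), or None for an empty set."""
        if not self.tracks:
            return None
        frames = [f for t in self.tracks for f in t.frames]
        return min(frames), max(frames)

    def detections_by_frame(self) -> dict[int, list[Detection]]:
        out: dict[int, list[Detection]] = {}
        for t in self.tracks:
            for d in t.detections:
                out.setdefault(d.frame, []).append(d)
        # deterministic within-frame order
        for dets in out.values():
            dets.sort(key=lambda d: d.label)
        return out

    def all_detections(self) -> list[Detection]:
        return [d for t in self.tracks for d in t.detections]


@dataclass(frozen=True)
class BBoxAnnotation:
    """One YOLO-style bounding box, denormalized to pixel units."""

    frame: int
    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    source_normalized: bool = True

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise TrackValidationError(
                f"degenerate box at frame {self.frame}: w={self.w}, h={self.h}"
            )

    def contains(self, x: float, y: float) -> bool:
        return (
            self.cx - self.w / 2 <= x <= self.cx + self.w / 2
            and self.cy - self.h / 2 <= y <= self.cy + self.h / 2
        )


# ---------------------------------------------------------------------------
# trajectory CSV


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical names to actual file column names, case-insensitively."""
    dialect = dialect or {}
    lower = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canon in CANONICAL_COLUMNS:
        wanted = dialect.get(canon, canon).lower().strip()
        if wanted not in lower:
            raise TrackFormatError(
                f"required column {dialect.get(canon, canon)!r} not found; "
                f"file has columns {list(columns)}"
            )
        resolved[canon] = lower[wanted]
    return resolved


def read_tracks(path: str | Path, dialect: Mapping[str, str] | None = None) -> TrackSet:
    """Read a trajectory CSV into a :class:`TrackSet`.

    Parameters
    ----------
    path:
        CSV file with a header row; columns resolvable to x, y, label, frame
        case-insensitively and in any order.
    dialect:
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"label": "particle"}``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _resolve_columns(df.columns, dialect)

    def _numeric(canon: str, as_int: bool) -> np.ndarray:
        raw = df[cols[canon]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            i = int(bad.idxmax())
            raise TrackFormatError(
                f"{path.name}: non-numeric {canon!r} value {raw[i]!r} "
                f"on line {i + 2}"  # +1 header, +1 one-based
            )
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise TrackFormatError(f"{path.name}: empty {canon!r} value on line {i + 2}")
        if as_int:
            ints = vals.to_numpy()
            if not np.allclose(ints, np.round(ints)):
                i = int(np.argmin(np.isclose(ints, np.round(ints))))
                raise TrackFormatError(
                    f"{path.name}: non-integer frame {ints[i]!r} on line {i + 2}"
                )
            return np.round(ints).astype(int)
        return vals.to_numpy(dtype=float)

    if len(df) == 0:
        return TrackSet(tracks=())
    xs = _numeric("x", as_int=False)
    ys = _numeric("y", as_int=False)
    frames = _numeric("frame", as_int=True)
    labels = df[cols["label"]].astype(str).str.strip()

    dup = pd.DataFrame({"label": labels, "frame": frames}).duplicated(keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup][:10]]
        raise TrackValidationError(
            f"{path.name}: duplicate (label, frame) pairs on lines {rows}"
        )

    dets = [
        Detection(frame=int(f), x=float(x), y=float(y), label=str(l))
        for x, y, l, f in zip(xs, ys, labels, frames)
    ]
    return TrackSet.from_detections(dets)


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write a TrackSet to the trajectory CSV dialect (header ``x,y,label,frame``).

    Coordinates are written with 10 significant digits so that a round trip
    preserves distances far below the 1e-4 px contract.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("x,y,label,frame\n")
        for track in ts.tracks:
            for d in track.detections:
                fh.write(f"{d.x:.10g},{d.y:.10g},{d.label},{d.frame}\n")
    return path


# ---------------------------------------------------------------------------
# YOLO-style bounding boxes

_DIGITS = re.compile(r"(\d+)")


def frame_index_from_name(name: str) -> int:
    """Parse the frame index from a filename (last run of digits in the stem)."""
    stem = Path(name).stem
    groups = _DIGITS.findall(stem)
    if not groups:
        raise TrackFormatError(f"cannot parse a frame index from filename {name!r}")
    return int(groups[-1])


def read_bbox_annotations(
    directory: str | Path, image_width: float, image_height: float
) -> list[BBoxAnnotation]:
    """Read a directory of per-frame YOLO annotation files.

    Each file holds rows ``class_id cx cy w h`` in normalized [0, 1]
    coordinates; the frame index is parsed from the filename. Returned
    boxes are denormalized to pixels.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix in {".txt", ".csv", ""})
    if not files:
        logger.warning("no annotation files found in %s", directory)
        return []
    out: list[BBoxAnnotation] = []
    for path in files:
        frame = frame_index_from_name(path.name)
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise TrackFormatError(
                    f"{path.name}:{lineno}: expected 5 fields 'class cx cy w h', "
                    f"got {len(parts)}"
                )
            try:
                class_id = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:])
            except ValueError as exc:
                raise TrackFormatError(f"{path.name}:{lineno}: {exc}") from exc
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not 0.0 <= v <= 1.0:
                    raise TrackValidationError(
                        f"{path.name}:{lineno}: normalized {name}={v} outside [0, 1]"
                    )
            out.append(
                BBoxAnnotation(
                    frame=frame,
                    class_id=class_id,
                    cx=cx * image_width,
                    cy=cy * image_height,
                    w=w * image_width,
                    h=h * image_height,
                    source_normalized=True,
                )
            )
    out.sort(key=lambda b: b.frame)
    return out
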