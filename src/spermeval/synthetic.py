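"""Synthetic sperm-like scenes with exactly countable tracking errors.

Three pieces:

* :func:`simulate_tracks` — reference trajectory sets built from simple
  motion models with analytically known kinematics: progressive swimmers
  (straight mean path plus sinusoidal lateral head oscillation, the
  minimal model giving the characteristic VCL > VAP > VSL ordering),
  circling swimmers (hyperactivated-like), immotile cells (Gaussian
  jitter about a point) and debris (perfectly static). No hydrodynamics
  is attempted; the populations exist so that filters, metrics and
  kinematics have closed-form oracles.
* :func:`corrupt` — injects countable errors into a copy of a track set:
  isolated detection deletions (false negatives), isolated spurious
  detections (false positives), pairwise label swaps at the frame where
  two tracks pass closest (emulating crossover failures), and track
  fragmentation with a fresh label (emulating dropout/relabeling). Events
  are kept mutually non-adjacent in (track, frame) so the induced
  FN/FP/IDSW/edge counts recorded in the :class:`CorruptionLog` are
  additive and exactly predict the evaluation counts at any association
  cutoff exceeding the localization noise.
* :func:`render_frames` — draws detections as isotropic Gaussian spots on
  noisy grayscale frames so the detector/linker can be exercised
  end-to-end.

All randomness flows from a single integer seed through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .trackio import Detection, TrackSet

__all__ = [
    "Population",
    "SceneSpec",
    "CorruptionSpec",
    "CorruptionLog",
    "simulate_tracks",
    "corrupt",
    "render_frames",
    "default_scene",
]


@dataclass(frozen=True)
class Population:
    """One motion-model population of a scene.

    ``params`` values may be scalars or (low, high) ranges sampled per
    track. Units: speeds in px/frame, amplitudes/radii/jitter in px,
    oscillation frequency in Hz, angular speed in rad/frame.

    Models and parameters:

    * ``progressive`` — speed, amplitude, frequency
    * ``circling``    — radius, omega
    * ``immotile``    — jitter
    * ``debris``      — (none)
    """

    model: str
    count: int
    params: Mapping[str, float | tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class SceneSpec:
    """A stated synthetic world: field, duration, frame rate, populations."""

    field_size: tuple[int, int] = (512, 512)  # (width, height) px
    n_frames: int = 270  # 30 s at 9 fps
    fps: float = 9.0
    seed: int = 0
    populations: tuple[Population, ...] = ()
    boundary: str = "reflect"  # "reflect" | "terminate"

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.boundary not in ("reflect", "terminate"):
            raise ValueError(f"boundary must be reflect|terminate, got {self.boundary}")


def default_scene(seed: int = 0) -> SceneSpec:
    """A crowded 30 s field mixing all four populations.

    Speeds span slow progressive to fast progressive swimmers (up to
    ~15 px/frame, within the baseline 25 px search range), circling tracks
    stand in for hyperactivated motility, and immotile cells plus debris
    provide the non-moving confounders the motion filter must remove.
    """
    return SceneSpec(
        seed=seed,
        populations=(
            Population("progressive", 18, {"speed": (3.0, 15.0), "amplitude": (0.0, 4.0), "frequency": (0.5, 3.0)}),
            Population("circling", 6, {"radius": (10.0, 40.0), "omega": (0.1, 0.4)}),
            Population("immotile", 8, {"jitter": (0.0, 1.0)}),
            Population("debris", 4, {}),
        ),
    )


def _sample(rng: np.random.Generator, v) -> float:
    if isinstance(v, (tuple, list)):
        lo, hi = v
        return float(rng.uniform(lo, hi))
    return float(v)


def _fold(p: np.ndarray, size: float) -> np.ndarray:
    """Reflect coordinates into [0, size] (triangle fold, keeps continuity)."""
    period = 2.0 * size
    q = np.mod(p, period)
    return np.where(q > size, period - q, q)


def _progressive(rng, spec: SceneSpec, params) -> np.ndarray:
    w, h = spec.field_size
    t = np.arange(spec.n_frames, dtype=float)
    speed = _sample(rng, params.get("speed", (3.0, 15.0)))
    amp = _sample(rng, params.get("amplitude", (0.0, 4.0)))
    freq = _sample(rng, params.get("frequency", (0.5, 3.0)))
    heading = rng.uniform(0, 2 * np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    start = rng.uniform([0, 0], [w, h])
    u = np.array([np.cos(heading), np.sin(heading)])
    n = np.array([-u[1], u[0]])
    lateral = amp * np.sin(2 * np.pi * freq * t / spec.fps + phase)
    return start + t[:, None] * speed * u + lateral[:, None] * n


def _circling(rng, spec: SceneSpec, params) -> np.ndarray:
    w, h = spec.field_size
    t = np.arange(spec.n_frames, dtype=float)
    radius = _sample(rng, params.get("radius", (10.0, 40.0)))
    omega = _sample(rng, params.get("omega", (0.1, 0.4)))
    phase = rng.uniform(0, 2 * np.pi)
    margin = min(radius + 1, min(w, h) / 2)
    center = rng.uniform([margin, margin], [w - margin, h - margin])
    ang = omega * t + phase
    return center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _immotile(rng, spec: SceneSpec, params) -> np.ndarray:
    w, h = spec.field_size
    sigma = _sample(rng, params.get("jitter", (0.0, 1.0)))
    point = rng.uniform([0, 0], [w, h])
    return point + rng.normal(0.0, sigma, size=(spec.n_frames, 2))


def _debris(rng, spec: SceneSpec, params) -> np.ndarray:
    w, h = spec.field_size
    point = rng.uniform([0, 0], [w, h])
    return np.tile(point, (spec.n_frames, 1))


_MODELS = {
    "progressive": _progressive,
    "circling": _circling,
    "immotile": _immotile,
    "debris": _debris,
}

_PREFIX = {"progressive": "prog", "circling": "circ", "immotile": "immo", "debris": "debr"}


def simulate_tracks(spec: SceneSpec) -> TrackSet:
    """Generate the reference TrackSet of a scene, deterministically per seed.

    Closed forms (for um_per_px=1, any fps): a progressive track with
    amplitude 0 and speed v px/frame has VCL = VSL = VAP = v * fps; a
    circling track has VCL = 2 r sin(omega/2) * fps and VSL -> 0 over
    whole turns.
    """
    if sum(p.count for p in spec.populations) == 0:
        raise ValueError("scene holds zero tracks")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.field_size
    dets: list[Detection] = []
    idx = 0
    for pop in spec.populations:
        for _ in range(pop.count):
            xy = _MODELS[pop.model](rng, spec, pop.params)
            label = f"{_PREFIX[pop.model]}_{idx}"
            idx += 1
            if spec.boundary == "reflect":
                xy = np.column_stack([_fold(xy[:, 0], w), _fold(xy[:, 1], h)])
                frames = range(spec.n_frames)
            else:
                inside = (
                    (xy[:, 0] >= 0) & (xy[:, 0] <= w) & (xy[:, 1] >= 0) & (xy[:, 1] <= h)
                )
                # terminate at first exit
                stop = int(np.argmin(inside)) if not inside.all() else spec.n_frames
                xy, frames = xy[:stop], range(stop)
                if stop == 0:
                    continue
            for f, (x, y) in zip(frames, xy):
                dets.append(Detection(frame=f, x=float(x), y=float(y), label=label))
    return TrackSet.from_detections(dets)


# ---------------------------------------------------------------------------
# corruption engine


@dataclass(frozen=True)
class CorruptionSpec:
    """Counts of tracking errors to inject, plus localization noise.

    ``fp_margin`` is the minimum distance of a spurious detection from any
    true detection of its frame; the exact-count contract holds for
    association cutoffs between the (3-sigma clipped) localization noise
    and this margin.
    """

    n_deletions: int = 0
    n_spurious: int = 0
    n_swaps: int = 0
    n_fragments: int = 0
    localization_noise: float = 0.0
    fp_margin: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_deletions", "n_spurious", "n_swaps", "n_fragments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.localization_noise < 0:
            raise ValueError("localization_noise must be >= 0")


@dataclass
class CorruptionLog:
    """Exact record of applied events and the evaluation counts they induce."""

    events: list[dict] = field(default_factory=list)
    fn_induced: int = 0
    fp_induced: int = 0
    idsw_induced: int = 0
    fn_edges_induced: int = 0
    fp_edges_induced: int = 0
    shortfall: dict[str, int] = field(default_factory=dict)


class _MutableTrack:
    """Working representation during corruption: frame-ordered point list."""

    __slots__ = ("label", "points", "claimed")

    def __init__(self, label: str, points: list[tuple[int, float, float]]):
        self.label = label
        self.points = points  # [(frame, x, y)], frame-ordered
        self.claimed: set[int] = set()  # frames reserved by an applied event

    def frames(self) -> list[int]:
        return [p[0] for p in self.points]


def _claim(track: _MutableTrack, frames: Sequence[int]) -> None:
    track.claimed.update(frames)


def _free(track: _MutableTrack, frames: Sequence[int]) -> bool:
    return not track.claimed.intersection(frames)


def corrupt(ts: TrackSet, cs: CorruptionSpec) -> tuple[TrackSet, CorruptionLog]:
    """Apply a corruption spec to a copy of ``ts`` and log exact effects.

    Events are rejected (and retried elsewhere) whenever they would touch
    a frame neighborhood already claimed by an earlier event on the same
    track, so per-event induced counts add up exactly. If the set cannot
    host all requested events, the shortfall is recorded in the log.
    """
    rng = np.random.default_rng(cs.seed)
    log = CorruptionLog()
    work: list[_MutableTrack] = [
        _MutableTrack(t.label, [(d.frame, d.x, d.y) for d in t.detections])
        for t in ts.tracks
    ]
    spurious: list[tuple[int, float, float]] = []
    next_fresh = 0

    def _attempt(n_events: int, kind: str, apply_one) -> None:
        nonlocal next_fresh
        applied = 0
        tries = 0
        while applied < n_events and tries < 200 * max(1, n_events):
            tries += 1
            if apply_one():
                applied += 1
        if applied < n_events:
            log.shortfall[kind] = n_events - applied

    # --- swaps: exchange tails of two tracks at their closest co-recorded frame
    def _try_swap() -> bool:
        candidates = [t for t in work if len(t.points) >= 2]
        if len(candidates) < 2:
            return False
        ia, ib = rng.choice(len(candidates), size=2, replace=False)
        a, b = candidates[ia], candidates[ib]
        fa = {p[0]: i for i, p in enumerate(a.points)}
        fb = {p[0]: i for i, p in enumerate(b.points)}
        # need both tracks recorded at t-1 and t, with room unclaimed
        shared = [
            t
            for t in fa
            if t - 1 in fa and t in fb and t - 1 in fb
            and _free(a, range(t - 2, t + 2)) and _free(b, range(t - 2, t + 2))
        ]
        if not shared:
            return False
        # pick the near-crossing: frame where the two tracks are closest
        def gap(t):
            pa, pb = a.points[fa[t]], b.points[fb[t]]
            return (pa[1] - pb[1]) ** 2 + (pa[2] - pb[2]) ** 2

        t = min(shared, key=gap)
        ia_, ib_ = fa[t], fb[t]
        a.points, b.points = (
            a.points[:ia_] + b.points[ib_:],
            b.points[:ib_] + a.points[ia_:],
        )
        _claim(a, range(t - 2, t + 2))
        _claim(b, range(t - 2, t + 2))
        # claims travel with the exchanged tails: share the union so later
        # events cannot land adjacent to an event recorded on the other label
        union = a.claimed | b.claimed
        a.claimed = set(union)
        b.claimed = set(union)
        log.events.append(
            {"kind": "swap", "labels": [a.label, b.label], "frame": t,
             "distance": float(np.sqrt(gap(t)))}
        )
        log.idsw_induced += 2
        log.fn_edges_induced += 2
        log.fp_edges_induced += 2
        return True

    _attempt(cs.n_swaps, "swaps", _try_swap)

    # --- fragments: split a track at a recorded-frame boundary, fresh label
    def _try_fragment() -> bool:
        nonlocal next_fresh
        candidates = [t for t in work if len(t.points) >= 2]
        if not candidates:
            return False
        t = candidates[rng.integers(len(candidates))]
        i = int(rng.integers(1, len(t.points)))
        f_prev, f_cut = t.points[i - 1][0], t.points[i][0]
        if not _free(t, range(f_prev - 1, f_cut + 2)):
            return False
        fresh = _MutableTrack(f"frag_{next_fresh}", t.points[i:])
        fresh.claimed = set(t.claimed)  # claims travel with the tail
        next_fresh += 1
        t.points = t.points[:i]
        _claim(t, range(f_prev - 1, f_cut + 2))
        _claim(fresh, range(f_prev - 1, f_cut + 2))
        work.append(fresh)
        log.events.append(
            {"kind": "fragment", "label": t.label, "new_label": fresh.label,
             "frame": f_cut}
        )
        log.idsw_induced += 1
        log.fn_edges_induced += 1
        return True

    _attempt(cs.n_fragments, "fragments", _try_fragment)

    # --- deletions: remove one recorded detection, neighbors unclaimed
    def _try_deletion() -> bool:
        candidates = [t for t in work if len(t.points) >= 2]
        if not candidates:
            return False
        t = candidates[rng.integers(len(candidates))]
        i = int(rng.integers(len(t.points)))
        f = t.points[i][0]
        has_prev = i > 0
        has_next = i < len(t.points) - 1
        lo = t.points[i - 1][0] if has_prev else f - 1
        hi = t.points[i + 1][0] if has_next else f + 1
        if not _free(t, range(lo, hi + 1)):
            return False
        del t.points[i]
        _claim(t, range(lo, hi + 1))
        log.events.append({"kind": "deletion", "label": t.label, "frame": f})
        log.fn_induced += 1
        log.fn_edges_induced += int(has_prev) + int(has_next)
        log.fp_edges_induced += int(has_prev and has_next)
        return True

    _attempt(cs.n_deletions, "deletions", _try_deletion)

    # --- spurious detections: singleton far from everything in their frame
    all_pts = np.array(
        [(d.frame, d.x, d.y) for d in ts.all_detections()], dtype=float
    ).reshape(-1, 3)
    if len(all_pts):
        fmin, fmax = int(all_pts[:, 0].min()), int(all_pts[:, 0].max())
        xy_lo = all_pts[:, 1:].min(axis=0) - cs.fp_margin
        xy_hi = all_pts[:, 1:].max(axis=0) + cs.fp_margin
    else:
        fmin, fmax, xy_lo, xy_hi = 0, 0, np.zeros(2), np.ones(2) * 100

    def _try_spurious() -> bool:
        f = int(rng.integers(fmin, fmax + 1))
        p = rng.uniform(xy_lo, xy_hi)
        frame_pts = all_pts[all_pts[:, 0] == f][:, 1:]
        near_true = (
            len(frame_pts)
            and np.min(np.linalg.norm(frame_pts - p, axis=1)) < cs.fp_margin
        )
        frame_spur = np.array([(x, y) for ff, x, y in spurious if ff == f]).reshape(-1, 2)
        near_spur = (
            len(frame_spur)
            and np.min(np.linalg.norm(frame_spur - p, axis=1)) < cs.fp_margin
        )
        if near_true or near_spur:
            return False
        spurious.append((f, float(p[0]), float(p[1])))
        log.events.append({"kind": "spurious", "frame": f, "x": float(p[0]), "y": float(p[1])})
        log.fp_induced += 1
        return True

    _attempt(cs.n_spurious, "spurious", _try_spurious)

    # --- assemble output, optionally jittered (noise clipped at 3 sigma)
    dets: list[Detection] = []
    for t in work:
        if not t.points:
            continue
        for f, x, y in t.points:
            dets.append(Detection(frame=f, x=x, y=y, label=t.label))
    for i, (f, x, y) in enumerate(spurious):
        dets.append(Detection(frame=f, x=x, y=y, label=f"spur_{i}"))
    if cs.localization_noise > 0:
        sig = cs.localization_noise
        noise = np.clip(rng.normal(0, sig, size=(len(dets), 2)), -3 * sig, 3 * sig)
        dets = [
            replace(d, x=d.x + float(nx), y=d.y + float(ny))
            for d, (nx, ny) in zip(dets, noise)
        ]
    return TrackSet.from_detections(dets), log


# ---------------------------------------------------------------------------
# rendering


def render_frames(
    ts: TrackSet,
    field_size: tuple[int, int],
    amplitude: float = 200.0,
    spot_sigma: float = 2.5,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Render each detection as an isotropic Gaussian spot on noisy frames.

    Returns a mapping frame -> float image of shape (height, width). The
    frame range spans the TrackSet (empty set: no frames). Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    w, h = field_size
    out: dict[int, np.ndarray] = {}
    fr = ts.frame_range
    if fr is None:
        return out
    by_frame = ts.detections_by_frame()
    half = int(np.ceil(4 * spot_sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    for f in range(fr[0], fr[1] + 1):
        img = rng.normal(0.0, noise_sigma, size=(h, w)) if noise_sigma > 0 else np.zeros((h, w))
        for d in by_frame.get(f, ()):
            cx, cy = int(round(d.x)), int(round(d.y))
            dx, dy = d.x - cx, d.y - cy
            spot = amplitude * np.exp(
                -(((xx - dx) ** 2 + (yy - dy) ** 2) / (2 * spot_sigma**2))
            )
            y0, y1 = cy - half, cy + half + 1
            x0, x1 = cx - half, cx + half + 1
            sy0, sy1 = max(0, -y0), 2 * half + 1 - max(0, y1 - h)
            sx0, sx1 = max(0, -x0), 2 * half + 1 - max(0, x1 - w)
            if sy1 <= sy0 or sx1 <= sx0:
                continue
            img[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] += spot[
                sy0:sy1, sx0:sx1
            ]
        out[f] = img
    return out
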