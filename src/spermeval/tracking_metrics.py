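"""Sperm-adapted multi-object and cell-tracking scores.

Seven scores are computed from a single centroid-based
:class:`~spermeval.association.MatchTable`:

* **DET, LNK, TRA** — graph-reconstruction scores in the acyclic-oriented
  graph matching (AOGM) style: the weighted number of node/edge edit
  operations needed to turn the predicted track graph into the reference
  graph, normalized by the cost of building the reference from scratch.
  Under one-to-one point matching the "node split" operation cannot occur,
  and sperm tracks have no division events, so only node additions (FN),
  node deletions (FP), edge additions (missing links) and edge deletions
  (spurious links) carry cost.
* **TF** — track fractions: mean over reference tracks of the longest
  contiguous stretch covered by a single predicted identity.
* **MOTA** — 1 - (FN + FP + ID switches) / N_gt; unbounded below.
* **IDF1** — F1 over a global one-to-one identity assignment between
  reference and predicted tracks.
* **HOTA** — geometric mean of detection accuracy and association
  accuracy, evaluated at the single association cutoff tau.

A perfect prediction scores 1.0 on all seven. Scores that are
mathematically undefined for an input (no reference detections, no
reference edges) raise :class:`~spermeval.errors.UndefinedMetricError`.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .association import DEFAULT_CUTOFF, MatchTable, build_match_table
from .errors import UndefinedMetricError
from .trackio import TrackSet

__all__ = [
    "MetricWeights",
    "EdgeCounts",
    "MetricReport",
    "classify_edges",
    "det_score",
    "lnk_score",
    "tra_score",
    "tf_score",
    "mota_score",
    "idf1_score",
    "hota_score",
    "evaluate",
]


@dataclass(frozen=True)
class MetricWeights:
    """AOGM edit-operation costs (Cell Tracking Challenge convention)."""

    w_fn: float = 10.0  # add a missing node
    w_fp: float = 1.0  # delete a spurious node
    w_ea: float = 1.5  # add a missing edge
    w_ed: float = 1.0  # delete a spurious edge

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class EdgeCounts:
    gt_edges: int
    pred_edges: int
    correct_edges: int
    fn_edges: int
    fp_edges: int


@dataclass(frozen=True)
class MetricReport:
    """The seven scores plus the event counts they derive from."""

    det: float
    lnk: float
    tra: float
    tf: float
    mota: float
    idf1: float
    hota: float
    tp: int
    fn: int
    fp: int
    idsw: int
    gt_edges: int
    pred_edges: int
    fn_edges: int
    fp_edges: int

    @property
    def scores(self) -> dict[str, float]:
        return {
            "det": self.det,
            "lnk": self.lnk,
            "tra": self.tra,
            "tf": self.tf,
            "mota": self.mota,
            "idf1": self.idf1,
            "hota": self.hota,
        }

    @property
    def counts(self) -> dict[str, int]:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "idsw": self.idsw,
            "gt_edges": self.gt_edges,
            "pred_edges": self.pred_edges,
            "fn_edges": self.fn_edges,
            "fp_edges": self.fp_edges,
        }


def classify_edges(gt: TrackSet, pred: TrackSet, mt: MatchTable) -> EdgeCounts:
    """Classify track-graph edges as correct, missing (FN) or spurious (FP).

    An edge connects temporally consecutive *recorded* detections of one
    track (gap-spanning edges included). A predicted edge is correct iff
    both endpoints are matched and their matched reference detections are
    consecutive recorded detections of the same reference track in the same
    temporal order. Because association is per-frame and one-to-one, each
    correct predicted edge covers exactly one reference edge, and no
    reference edge can be covered twice.
    """
    gt_edges = {(t.label, f1, f2) for t in gt for f1, f2 in t.edges()}
    pred_to_gt = mt.pred_to_gt

    n_pred_edges = 0
    covered: set[tuple[str, int, int]] = set()
    fp_edges = 0
    for t in pred:
        for f1, f2 in t.edges():
            n_pred_edges += 1
            g1 = pred_to_gt.get((f1, t.label))
            g2 = pred_to_gt.get((f2, t.label))
            if g1 is not None and g1 == g2 and (g1, f1, f2) in gt_edges:
                covered.add((g1, f1, f2))
            else:
                fp_edges += 1
    return EdgeCounts(
        gt_edges=len(gt_edges),
        pred_edges=n_pred_edges,
        correct_edges=len(covered),
        fn_edges=len(gt_edges) - len(covered),
        fp_edges=fp_edges,
    )


def _n_gt(mt: MatchTable) -> int:
    return mt.tp + mt.fn


def det_score(mt: MatchTable, w: MetricWeights = MetricWeights()) -> float:
    """Node-placement score: 1 - min(w_fn*FN + w_fp*FP, w_fn*N_gt) / (w_fn*N_gt)."""
    n_gt = _n_gt(mt)
    if n_gt == 0:
        raise UndefinedMetricError("DET", "ground truth holds no detections")
    denom = w.w_fn * n_gt
    cost = w.w_fn * mt.fn + w.w_fp * mt.fp
    return 1.0 - min(cost, denom) / denom


def lnk_score(edges: EdgeCounts, w: MetricWeights = MetricWeights()) -> float:
    """Edge-placement score: 1 - min(w_ea*FNe + w_ed*FPe, w_ea*E_gt) / (w_ea*E_gt)."""
    if edges.gt_edges == 0:
        raise UndefinedMetricError("LNK", "ground truth holds no edges (all singletons)")
    denom = w.w_ea * edges.gt_edges
    cost = w.w_ea * edges.fn_edges + w.w_ed * edges.fp_edges
    return 1.0 - min(cost, denom) / denom


def tra_score(
    mt: MatchTable, edges: EdgeCounts, w: MetricWeights = MetricWeights()
) -> float:
    """Combined node+edge reconstruction score, 1 - min(AOGM, AOGM0)/AOGM0."""
    n_gt = _n_gt(mt)
    if n_gt == 0:
        raise UndefinedMetricError("TRA", "ground truth holds no detections")
    aogm = (
        w.w_fn * mt.fn
        + w.w_fp * mt.fp
        + w.w_ea * edges.fn_edges
        + w.w_ed * edges.fp_edges
    )
    aogm0 = w.w_fn * n_gt + w.w_ea * edges.gt_edges
    return 1.0 - min(aogm, aogm0) / aogm0


def tf_score(gt: TrackSet, pred: TrackSet, mt: MatchTable) -> float:
    """Track fractions: mean longest single-identity contiguous coverage.

    Per reference track, find the longest run of consecutive recorded
    detections all matched to the same predicted label; TF is the mean of
    run length / track length over reference tracks.
    """
    if len(gt) == 0:
        raise UndefinedMetricError("TF", "ground truth holds no tracks")
    gt_to_pred = mt.gt_to_pred
    fractions = []
    for t in gt:
        best = run = 0
        prev: str | None = None
        for d in t.detections:
            cur = gt_to_pred.get((d.frame, t.label))
            if cur is not None and cur == prev:
                run += 1
            elif cur is not None:
                run = 1
            else:
                run = 0
            prev = cur
            best = max(best, run)
        fractions.append(best / len(t))
    return float(np.mean(fractions))


def count_id_switches(gt: TrackSet, mt: MatchTable) -> int:
    """Matched reference detections whose predicted label differs from the
    predicted label of that track's most recent previous match (gaps skipped)."""
    gt_to_pred = mt.gt_to_pred
    idsw = 0
    for t in gt:
        prev: str | None = None
        for d in t.detections:
            cur = gt_to_pred.get((d.frame, t.label))
            if cur is not None:
                if prev is not None and cur != prev:
                    idsw += 1
                prev = cur
    return idsw


def mota_score(mt: MatchTable, gt: TrackSet) -> float:
    """Multi-object tracking accuracy: 1 - (FN + FP + IDSW) / N_gt."""
    n_gt = _n_gt(mt)
    if n_gt == 0:
        raise UndefinedMetricError("MOTA", "ground truth holds no detections")
    idsw = count_id_switches(gt, mt)
    return 1.0 - (mt.fn + mt.fp + idsw) / n_gt


def idf1_score(gt: TrackSet, pred: TrackSet, mt: MatchTable) -> float:
    """Identification F1 over a global one-to-one track-identity assignment.

    overlap(g, p) counts frames where g's detection is matched to p's;
    the assignment maximizing total overlap defines IDTP, and
    IDF1 = 2*IDTP / (N_gt + N_pred).
    """
    n_gt, n_pred = gt.n_detections, pred.n_detections
    if n_gt + n_pred == 0:
        raise UndefinedMetricError("IDF1", "both track sets are empty")
    glabels, plabels = gt.labels, pred.labels
    if glabels and plabels:
        gi = {l: i for i, l in enumerate(glabels)}
        pi = {l: i for i, l in enumerate(plabels)}
        overlap = np.zeros((len(glabels), len(plabels)))
        for (frame, gl), pl in mt.gt_to_pred.items():
            overlap[gi[gl], pi[pl]] += 1
        rows, cols = linear_sum_assignment(overlap, maximize=True)
        idtp = float(overlap[rows, cols].sum())
    else:
        idtp = 0.0
    return 2.0 * idtp / (n_gt + n_pred)


def hota_score(gt: TrackSet, pred: TrackSet, mt: MatchTable) -> float:
    """Higher-order tracking accuracy at the single association cutoff.

    DetA = TP / (TP + FN + FP). For each true positive c with identity
    pair (g, p): TPA(c) = TPs sharing (g, p); FNA(c) = detections of g not
    in a (g, p) TP; FPA(c) = detections of p not in a (g, p) TP;
    A(c) = TPA / (TPA + FNA + FPA). HOTA = sqrt(DetA * mean A(c)).
    """
    tp, fn, fp = mt.tp, mt.fn, mt.fp
    if tp + fn + fp == 0:
        raise UndefinedMetricError("HOTA", "no detections on either side")
    det_a = tp / (tp + fn + fp)
    if tp == 0:
        return 0.0
    pair_count: dict[tuple[str, str], int] = {}
    for (frame, gl), pl in mt.gt_to_pred.items():
        pair_count[(gl, pl)] = pair_count.get((gl, pl), 0) + 1
    gt_size = {t.label: len(t) for t in gt}
    pred_size = {t.label: len(t) for t in pred}
    ass_sum = 0.0
    for (gl, pl), tpa in pair_count.items():
        fna = gt_size[gl] - tpa
        fpa = pred_size[pl] - tpa
        ass_sum += tpa * (tpa / (tpa + fna + fpa))
    ass_a = ass_sum / tp
    return math.sqrt(det_a * ass_a)


def evaluate(
    gt: TrackSet,
    pred: TrackSet,
    cutoff: float = DEFAULT_CUTOFF,
    weights: MetricWeights = MetricWeights(),
    filter_config=None,
) -> MetricReport:
    """End-to-end evaluation: optional motion filter, association, all scores.

    When ``filter_config`` (a :class:`spermeval.kinematics.FilterConfig`) is
    given, the span-radius/min-length filter is applied identically to both
    the reference and the prediction before matching, down-weighting
    immotile cells and debris.
    """
    if filter_config is not None:
        from .kinematics import filter_tracks

        gt = filter_tracks(gt, filter_config)
        pred = filter_tracks(pred, filter_config)
    mt = build_match_table(gt, pred, cutoff)
    edges = classify_edges(gt, pred, mt)
    return MetricReport(
        det=det_score(mt, weights),
        lnk=lnk_score(edges, weights),
        tra=tra_score(mt, edges, weights),
        tf=tf_score(gt, pred, mt),
        mota=mota_score(mt, gt),
        idf1=idf1_score(gt, pred, mt),
        hota=hota_score(gt, pred, mt),
        tp=mt.tp,
        fn=mt.fn,
        fp=mt.fp,
        idsw=count_id_switches(gt, mt),
        gt_edges=edges.gt_edges,
        pred_edges=edges.pred_edges,
        fn_edges=edges.fn_edges,
        fp_edges=edges.fp_edges,
    )
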