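"""The seven adapted tracking scores against hand-worked and brute-force oracles."""

import math

import pytest

from spermeval.association import build_match_table
from spermeval.errors import UndefinedMetricError
from spermeval.kinematics import FilterConfig
from spermeval.tracking_metrics import (
    MetricWeights,
    classify_edges,
    det_score,
    evaluate,
    hota_score,
    idf1_score,
    lnk_score,
    mota_score,
    tf_score,
    tra_score,
)
from spermeval.trackio import Detection, TrackSet

from conftest import make_random_trackset, straight_track
from oracles import brute_scores


def det(frame, x, y, label):
    return Detection(frame=frame, x=x, y=y, label=label)


def ts_of(*tracks):
    return TrackSet(tracks=tuple(tracks))


@pytest.fixture
def gap_instance():
    """10-detection reference track; prediction lacks the frame-5 detection,
    so frames 4 and 6 are linked directly by a gap-spanning edge."""
    gt = ts_of(straight_track("a", n=10))
    pred = TrackSet.from_detections(
        [det(f, float(f), 0.0, "a") for f in range(10) if f != 5]
    )
    return gt, pred


@pytest.fixture
def split_55():
    """10-detection reference split into two predicted 5-detection identities."""
    gt = ts_of(straight_track("a", n=10))
    pred = TrackSet.from_detections(
        [det(f, float(f), 0.0, "p1" if f < 5 else "p2") for f in range(10)]
    )
    return gt, pred


class TestEdgeClassification:
    def test_perfect_prediction_has_no_edge_errors(self, random_trackset):
        mt = build_match_table(random_trackset, random_trackset, 5)
        e = classify_edges(random_trackset, random_trackset, mt)
        assert e.fn_edges == e.fp_edges == 0
        assert e.correct_edges == e.gt_edges == e.pred_edges

    def test_gap_instance_edge_counts(self, gap_instance):
        gt, pred = gap_instance
        mt = build_match_table(gt, pred, 2)
        e = classify_edges(gt, pred, mt)
        assert e.gt_edges == 9 and e.pred_edges == 8
        assert e.fn_edges == 2  # edges 4-5 and 5-6 have no counterpart
        assert e.fp_edges == 1  # the direct 4-6 link

    def test_crossing_label_exchange_edge_counts(self):
        """Two tracks crossing at frame 5 with predicted labels exchanged from
        there on: 2 reference edges lost, 2 spurious predicted edges."""
        gt = TrackSet.from_detections(
            [det(f, float(f), 0.0, "a") for f in range(10)]
            + [det(f, float(f), 10.0 - f, "b") for f in range(10)]
        )
        swapped = []
        for t in gt:
            for d in t.detections:
                lbl = d.label if d.frame < 5 else ("b" if d.label == "a" else "a")
                swapped.append(det(d.frame, d.x, d.y, lbl))
        pred = TrackSet.from_detections(swapped)
        mt = build_match_table(gt, pred, 2)
        assert mt.fn == mt.fp == 0
        e = classify_edges(gt, pred, mt)
        assert e.fn_edges == 2 and e.fp_edges == 2


class TestHandWorkedScores:
    def test_det_hand_value(self):
        """100 reference detections, 2 FN, 1 FP: DET = 1 - 21/1000."""
        gt = ts_of(*[straight_track(f"t{i}", n=10, start=(0, 40.0 * i)) for i in range(10)])
        dets = [d for t in gt for d in t.detections]
        kept = [d for d in dets if not (d.label == "t0" and d.frame in (3, 7))]
        pred = TrackSet.from_detections(
            [det(d.frame, d.x, d.y, d.label) for d in kept]
            + [det(0, 500.0, 500.0, "junk")]
        )
        mt = build_match_table(gt, pred, 5)
        assert (mt.fn, mt.fp) == (2, 1)
        assert det_score(mt) == pytest.approx(0.979, abs=1e-12)

    def test_lnk_and_tra_gap_instance(self, gap_instance):
        gt, pred = gap_instance
        mt = build_match_table(gt, pred, 2)
        e = classify_edges(gt, pred, mt)
        assert lnk_score(e) == pytest.approx(1 - 4 / 13.5, abs=1e-12)
        assert tra_score(mt, e) == pytest.approx(1 - 14 / 113.5, abs=1e-12)

    def test_tf_contiguous_run_64_split(self):
        """Reference covered by id A for 6 detections then B for 4: TF = 0.6."""
        gt = ts_of(straight_track("a", n=10))
        pred = TrackSet.from_detections(
            [det(f, float(f), 0.0, "A" if f < 6 else "B") for f in range(10)]
        )
        mt = build_match_table(gt, pred, 2)
        assert tf_score(gt, pred, mt) == pytest.approx(0.6, abs=1e-12)

    def test_split_55_idf1_hota_tf(self, split_55):
        gt, pred = split_55
        mt = build_match_table(gt, pred, 2)
        assert idf1_score(gt, pred, mt) == pytest.approx(0.5, abs=1e-12)
        assert hota_score(gt, pred, mt) == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert tf_score(gt, pred, mt) == pytest.approx(0.5, abs=1e-12)

    def test_mota_one_swap_on_2x100(self):
        """Label exchange between two tracks mid-video: 2 switches, MOTA 0.99."""
        gt = TrackSet.from_detections(
            [det(f, float(f), 50.0 * i, f"t{i}") for i in range(2) for f in range(100)]
        )
        pred = TrackSet.from_detections(
            [
                det(
                    d.frame,
                    d.x,
                    d.y,
                    d.label if d.frame < 50 else ("t1" if d.label == "t0" else "t0"),
                )
                for t in gt
                for d in t.detections
            ]
        )
        mt = build_match_table(gt, pred, 5)
        assert mota_score(mt, gt) == pytest.approx(0.99, abs=1e-12)


class TestDegenerateInputs:
    def test_empty_prediction_zeroes_all_scores(self, random_trackset):
        rep = evaluate(random_trackset, TrackSet(tracks=()))
        assert all(v == 0.0 for v in rep.scores.values())
        assert rep.fn == random_trackset.n_detections

    def test_undefined_metrics_raise(self):
        empty = TrackSet(tracks=())
        singletons = TrackSet.from_detections(
            [det(0, 0, 0, "a"), det(0, 50, 50, "b")]
        )
        mt = build_match_table(empty, empty, 5)
        with pytest.raises(UndefinedMetricError, match="DET"):
            det_score(mt)
        mt2 = build_match_table(singletons, singletons, 5)
        e = classify_edges(singletons, singletons, mt2)
        with pytest.raises(UndefinedMetricError, match="LNK"):
            lnk_score(e)
        with pytest.raises(UndefinedMetricError, match="HOTA"):
            hota_score(empty, empty, mt)

    def test_mota_unbounded_below(self):
        gt = ts_of(straight_track("a", n=5))
        pred = TrackSet.from_detections(
            [det(d.frame, d.x, d.y, d.label) for d in gt.tracks[0].detections]
            + [det(f, 300.0 + 40 * i, 300.0, f"fp{i}_{f}") for i in range(20) for f in range(5)]
        )
        mt = build_match_table(gt, pred, 5)
        assert mota_score(mt, gt) < 0


class TestProperties:
    def test_identity_is_all_ones(self, rng):
        for _ in range(10):
            ts = make_random_trackset(rng, int(rng.integers(1, 6)), 20)
            rep = evaluate(ts, ts, cutoff=3.0)
            assert all(v == 1.0 for v in rep.scores.values())
            assert rep.fn == rep.fp == rep.idsw == rep.fn_edges == rep.fp_edges == 0

    def test_added_false_positive_never_raises_scores(self, rng):
        """An extra isolated spurious detection cannot improve DET, TRA, MOTA,
        IDF1 or HOTA."""
        for trial in range(10):
            gt = make_random_trackset(rng, 3, 12, field=60)
            pred = make_random_trackset(rng, 3, 12, field=60)
            before = evaluate(gt, pred, cutoff=8.0)
            f = int(rng.integers(0, 12))
            extra = det(f, 500.0 + trial, 500.0, "extra_fp")
            pred2 = TrackSet.from_detections(pred.all_detections() + [extra])
            after = evaluate(gt, pred2, cutoff=8.0)
            for name in ("det", "tra", "mota", "idf1", "hota"):
                assert after.scores[name] <= before.scores[name] + 1e-12

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        """Each score equals independent exhaustive enumeration to 1e-9 on
        corrupted instances with <= 4 tracks x <= 8 frames."""
        for _ in range(40):
            gt = make_random_trackset(rng, int(rng.integers(1, 5)), 8, field=40, step=3)
            dets = []
            for t in gt:
                for d in t.detections:
                    if rng.random() < 0.15:
                        continue  # deletion
                    lbl = d.label
                    if rng.random() < 0.1:
                        lbl = f"re{int(rng.integers(3))}"  # relabeling
                    dets.append(
                        det(d.frame, d.x + rng.normal(0, 1), d.y + rng.normal(0, 1), lbl)
                    )
            if rng.random() < 0.5:
                dets.append(det(int(rng.integers(8)), 200.0, 200.0, "spur"))
            try:
                pred = TrackSet.from_detections(dets)
            except Exception:
                continue  # relabeling may collide on (label, frame); skip
            got = evaluate(gt, pred, cutoff=6.0)
            want = brute_scores(gt, pred, cutoff=6.0)
            for name, w in want.items():
                assert w is not None
                assert got.scores[name] == pytest.approx(w, abs=1e-9), name

    def test_scores_in_unit_interval_except_mota(self, rng):
        for _ in range(30):
            gt = make_random_trackset(rng, 3, 10, field=50)
            pred = make_random_trackset(rng, 4, 10, field=50)
            rep = evaluate(gt, pred, cutoff=10.0)
            for name, v in rep.scores.items():
                if name == "mota":
                    assert v <= 1.0
                else:
                    assert 0.0 <= v <= 1.0


class TestEvaluatePipeline:
    def test_filtering_drops_immotile_tracks_from_both_sides(self):
        moving = straight_track("m", n=12, step=(3.0, 0.0))
        static = TrackSet.from_detections(
            [det(f, 100.0, 100.0, "s") for f in range(12)]
        ).tracks[0]
        gt = ts_of(moving, static)
        rep = evaluate(gt, gt, filter_config=FilterConfig(epsilon=5, min_length=9))
        # only the moving track remains on both sides: still perfect scores
        assert all(v == 1.0 for v in rep.scores.values())
        assert rep.tp == 12

    def test_custom_weights_change_scores(self):
        """Raising the spurious-node cost lowers DET when FPs are present:
        DET = 1 - w_fp * FP / (w_fn * N_gt) below the clamp."""
        gt = ts_of(straight_track("a", n=10))
        pred = TrackSet.from_detections(
            list(gt.tracks[0].detections) + [det(0, 400.0, 400.0, "junk")]
        )
        mt = build_match_table(gt, pred, 5)
        light = det_score(mt, MetricWeights(w_fp=1))
        heavy = det_score(mt, MetricWeights(w_fp=5))
        assert light == pytest.approx(1 - 1 / 100, abs=1e-12)
        assert heavy == pytest.approx(1 - 5 / 100, abs=1e-12)
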