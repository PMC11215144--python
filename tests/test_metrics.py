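"""Detection P/R/F1/AP and counting R²/RMSE."""

import numpy as np
import pytest

from earcount import BoundingBox, eval_counts, eval_detections, eval_detections_dataset
from conftest import random_box


def box_at(cx, cy, w=10.0, h=10.0, conf=1.0):
    return BoundingBox(cx, cy, w, h, conf)


def ap_oracle(flags, n_truth):
    """All-point interpolated AP by direct accumulation over a TP/FP ranking."""
    tp = 0
    points = []
    for k, f in enumerate(flags, start=1):
        tp += f
        points.append((tp / n_truth, tp / k))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            p_max = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap


class TestEvalDetections:
    def test_perfect_single_detection(self):
        t = [box_at(5, 5)]
        ev = eval_detections([(box_at(5, 5), 0.9)], t)
        assert (ev.precision, ev.recall, ev.f1, ev.ap) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_ranking(self):
        # 3 truths; ranked predictions TP, FP, TP
        truth = [box_at(10, 10), box_at(40, 10), box_at(70, 10)]
        preds = [
            (box_at(10, 10), 0.9),          # TP
            (box_at(100, 100), 0.8),        # FP
            (box_at(40, 11), 0.7),          # TP (IoU 0.9/1.1 ~ 0.82)
        ]
        ev = eval_detections(preds, truth, iou_thresh=0.5)
        assert ev.tp == 2 and ev.fp == 1 and ev.fn == 1
        assert ev.precision == pytest.approx(2 / 3)
        assert ev.recall == pytest.approx(2 / 3)
        assert ev.ap == pytest.approx(1 / 3 + (1 / 3) * (2 / 3))  # 0.5556

    def test_empty_predictions(self):
        ev = eval_detections([], [box_at(1, 1), box_at(5, 5)])
        assert ev.precision == 0.0 and not ev.precision_defined
        assert ev.recall == 0.0 and ev.ap == 0.0 and ev.fn == 2

    def test_empty_truth_flagged(self):
        ev = eval_detections([(box_at(1, 1), 0.5)], [])
        assert not ev.recall_defined
        assert ev.fp == 1 and ev.ap == 0.0

    def test_matches_brute_force_oracle(self, rng):
        """AP equals direct PR accumulation on random small evaluation sets."""
        for _ in range(200):
            n_truth = int(rng.integers(1, 10))
            truth = [box_at(30 * i, 10) for i in range(n_truth)]
            preds = []
            for i in range(int(rng.integers(1, 10))):
                if rng.uniform() < 0.6 and i < n_truth:
                    b = box_at(30 * i + rng.uniform(-2, 2), 10)  # likely TP
                else:
                    b = box_at(1000 + 30 * i, 500)  # FP
                preds.append((b, float(rng.uniform(0.01, 0.99))))
            ev = eval_detections(preds, truth, iou_thresh=0.5)
            order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
            # recompute flags independently: greedy in score order
            claimed = set()
            flags = []
            for i in order:
                best, bj = 0.0, None
                for j, t in enumerate(truth):
                    if j in claimed:
                        continue
                    from earcount import iou

                    v = iou(preds[i][0], t)
                    if v > best:
                        best, bj = v, j
                if bj is not None and best >= 0.5:
                    claimed.add(bj)
                    flags.append(1)
                else:
                    flags.append(0)
            assert ev.ap == pytest.approx(ap_oracle(flags, n_truth), abs=1e-12)

    def test_appended_fp_never_increases_ap(self):
        truth = [box_at(10, 10), box_at(40, 10)]
        preds = [(box_at(10, 10), 0.9), (box_at(40, 10), 0.8)]
        base = eval_detections(preds, truth).ap
        worse = eval_detections(preds + [(box_at(500, 500), 0.1)], truth).ap
        assert worse <= base

    def test_top_tp_never_decreases_ap(self):
        truth = [box_at(10, 10), box_at(40, 10), box_at(70, 10)]
        preds = [(box_at(500, 500), 0.8), (box_at(40, 10), 0.7)]
        base = eval_detections(preds, truth).ap
        better = eval_detections([(box_at(10, 10), 0.95)] + preds, truth).ap
        assert better >= base

    def test_matching_confined_to_frames(self):
        # a prediction in frame 2 cannot claim a truth of frame 1
        ev = eval_detections_dataset(
            [[], [(box_at(5, 5), 0.9)]],
            [[box_at(5, 5)], []],
        )
        assert ev.tp == 0 and ev.fp == 1 and ev.fn == 1

    def test_11_point_variant(self):
        truth = [box_at(10, 10), box_at(40, 10), box_at(70, 10)]
        preds = [(box_at(10, 10), 0.9), (box_at(500, 500), 0.8), (box_at(40, 11), 0.7)]
        ap11 = eval_detections(preds, truth, interpolation="11point").ap
        # recalls 1/3 and 2/3 -> p_interp 1 at r<=1/3, 2/3 at r<=2/3, 0 above
        assert ap11 == pytest.approx((4 * 1.0 + 3 * (2 / 3)) / 11)


class TestEvalCounts:
    def test_exact_agreement(self):
        ev = eval_counts([3, 5, 7], [3, 5, 7])
        assert ev.r2 == 1.0 and ev.rmse == 0.0 and ev.n == 3

    def test_worked_example(self):
        ev = eval_counts([2, 2, 2], [1, 2, 3])
        assert ev.rmse == pytest.approx(np.sqrt(2 / 3))
        assert ev.r2 == pytest.approx(0.0)

    def test_constant_mean_predictor_r2_zero(self, rng):
        truth = rng.integers(10, 50, size=12).astype(float)
        pred = [float(np.mean(truth))] * 12
        assert eval_counts(pred, list(truth)).r2 == pytest.approx(0.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import mean_squared_error, r2_score

        for _ in range(20):
            y = rng.normal(100, 20, size=15)
            yh = y + rng.normal(0, 5, size=15)
            ev = eval_counts(list(yh), list(y))
            assert ev.r2 == pytest.approx(r2_score(y, yh))
            assert ev.rmse == pytest.approx(np.sqrt(mean_squared_error(y, yh)))

    def test_zero_variance_truth_flagged(self):
        ev = eval_counts([5, 5], [5, 5])
        assert not ev.r2_defined and ev.r2 == 1.0 and ev.rmse == 0.0
        ev = eval_counts([5, 6], [5, 5])
        assert not ev.r2_defined and ev.rmse > 0

    def test_length_validation(self):
        with pytest.raises(ValueError):
            eval_counts([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            eval_counts([1], [1])
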