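"""Evaluation metrics: detection P/R/F1/AP and counting agreement R²/RMSE.

Detection evaluation follows the Pascal-VOC protocol: predictions are
ranked by confidence and each is greedily matched to the highest-IoU
unclaimed ground-truth box of its own image; a match with IoU >= the
threshold is a true positive, anything else a false positive, and
unclaimed truths are false negatives. AP is the area under the
precision-recall curve, by default with all-point (continuous)
interpolation; the classic 11-point variant is available.

Counting agreement between model counts and manual counts over a set of
videos is summarised by the coefficient of determination

    R² = 1 − Σ(ŷᵢ−yᵢ)² / Σ(ȳ−yᵢ)²

and the root-mean-square error RMSE = sqrt(Σ(ŷᵢ−yᵢ)²/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoundingBox, iou_matrix

__all__ = [
    "DetectionEval",
    "CountEval",
    "eval_detections",
    "eval_detections_dataset",
    "eval_counts",
]

BoxOrScored = "BoundingBox | tuple[BoundingBox, float]"


@dataclass(frozen=True)
class DetectionEval:
    """Detection scores; ``recall_defined`` is False when there is no truth,
    ``precision_defined`` False when there are no predictions."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap: float
    pr_curve: tuple[tuple[float, float], ...]  # (recall, precision) per rank
    recall_defined: bool = True
    precision_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "ap": self.ap,
        }


@dataclass(frozen=True)
class CountEval:
    """Counting agreement; ``r2_defined`` is False when truth has no variance."""

    r2: float
    rmse: float
    n: int
    r2_defined: bool = True

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "n": self.n}


def _as_scored(predicted) -> list[tuple[BoundingBox, float]]:
    pairs = [p if isinstance(p, tuple) else (p, p.conf) for p in predicted]
    for _, s in pairs:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"scores must lie in [0, 1], got {s}")
    return pairs


def _greedy_match(
    pairs: list[tuple[BoundingBox, float]],
    truth: list[BoundingBox],
    iou_thresh: float,
) -> list[tuple[float, bool]]:
    """TP/FP flag per prediction of one image, greedily in score order.

    Returns (score, is_tp) in descending-score order; ties keep input order.
    """
    order = sorted(range(len(pairs)), key=lambda i: (-pairs[i][1], i))
    if not order:
        return []
    if not truth:
        return [(pairs[i][1], False) for i in order]
    ious = iou_matrix([pairs[i][0] for i in order], truth)
    claimed = np.zeros(len(truth), dtype=bool)
    out: list[tuple[float, bool]] = []
    for k, i in enumerate(order):
        row = np.where(claimed, -1.0, ious[k])
        j = int(np.argmax(row))
        hit = row[j] >= iou_thresh
        if hit:
            claimed[j] = True
        out.append((pairs[i][1], bool(hit)))
    return out


def _ap_all_point(recalls: np.ndarray, precisions: np.ndarray) -> float:
    # area under the step-interpolated PR curve: interpolated precision at
    # recall r is the max precision achieved at any recall >= r
    r = np.concatenate([[0.0], recalls])
    p = np.concatenate([[0.0], precisions])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def _ap_11_point(recalls: np.ndarray, precisions: np.ndarray) -> float:
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 11):
        mask = recalls >= r
        ap += float(np.max(precisions[mask])) if np.any(mask) else 0.0
    return ap / 11.0


def eval_detections_dataset(
    predicted_frames: list[list],
    truth_frames: list[list[BoundingBox]],
    iou_thresh: float = 0.5,
    interpolation: str = "all_point",
) -> DetectionEval:
    """Score ranked detections against ground truth over a set of images.

    Matching is confined to each image; the PR curve and AP accumulate over
    the global confidence ranking. Each element of ``predicted_frames`` is a
    list of boxes (scores taken from ``conf``) or of (box, score) pairs.
    """
    if interpolation not in ("all_point", "11point"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if len(predicted_frames) != len(truth_frames):
        raise ValueError("predicted and truth frame lists differ in length")

    flagged: list[tuple[float, bool]] = []
    n_truth = 0
    for preds, truth in zip(predicted_frames, truth_frames):
        flagged.extend(_greedy_match(_as_scored(preds), list(truth), iou_thresh))
        n_truth += len(truth)
    # global ranking; stable so within-image order is preserved on ties
    flagged.sort(key=lambda t: -t[0])

    tp_flags = np.array([f for _, f in flagged], dtype=bool)
    n_pred = tp_flags.size
    tp_cum = np.cumsum(tp_flags)
    ranks = np.arange(1, n_pred + 1)
    precisions = tp_cum / ranks if n_pred else np.array([])
    recalls = (tp_cum / n_truth) if (n_pred and n_truth) else np.zeros(n_pred)

    tp = int(tp_cum[-1]) if n_pred else 0
    fp = n_pred - tp
    fn = n_truth - tp
    precision_defined = n_pred > 0
    recall_defined = n_truth > 0
    precision = tp / n_pred if precision_defined else 0.0
    recall = tp / n_truth if recall_defined else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0

    if tp == 0:
        ap = 0.0
    elif interpolation == "all_point":
        ap = _ap_all_point(recalls, precisions)
    else:
        ap = _ap_11_point(recalls, precisions)

    return DetectionEval(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1, ap=ap,
        pr_curve=tuple(zip(recalls.tolist(), precisions.tolist())),
        recall_defined=recall_defined, precision_defined=precision_defined,
    )


def eval_detections(
    predicted: list,
    truth: list[BoundingBox],
    iou_thresh: float = 0.5,
    interpolation: str = "all_point",
) -> DetectionEval:
    """Single-image detection evaluation (see :func:`eval_detections_dataset`)."""
    return eval_detections_dataset([predicted], [truth], iou_thresh, interpolation)


def eval_counts(pred: list[float], truth: list[float]) -> CountEval:
    """R² and RMSE between model counts and ground-truth counts.

    RMSE is 0 iff the vectors agree elementwise, in which case R² is 1
    (reported as 1 even in the degenerate zero-variance case, flagged).
    """
    y_hat = np.asarray(pred, dtype=float)
    y = np.asarray(truth, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 counts for R²")
    sse = float(np.sum((y_hat - y) ** 2))
    rmse = float(np.sqrt(sse / y.size))
    sst = float(np.sum((np.mean(y) - y) ** 2))
    if sst == 0.0:
        return CountEval(r2=1.0 if sse == 0.0 else -np.inf, rmse=rmse,
                         n=int(y.size), r2_defined=False)
    return CountEval(r2=1.0 - sse / sst, rmse=rmse, n=int(y.size))
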