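"""Optimal one-to-one matching of predicted boxes to detections.

The per-frame data-association step of tracking-by-detection: build the
pairwise IoU matrix between Kalman-predicted track boxes and current-frame
detections, solve the linear assignment problem that maximises total IoU
(Hungarian algorithm), then dissolve any assigned pair whose IoU does not
exceed the gate (default 0.7 — a match must clearly be the same object).
Gating after the global solve is the default; ``pre_mask=True`` instead
masks sub-gate pairs out of the cost matrix before solving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .geometry import BoundingBox, NWDParams, iou_matrix, nwd

__all__ = ["MatchResult", "solve_assignment", "match_tracks"]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one matching round.

    ``matches`` holds (track index, detection index, score) triples; every
    index appears exactly once across the three collections.
    """

    matches: list[tuple[int, int, float]]
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


def solve_assignment(score: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one assignment maximising the total score.

    Solves min-cost assignment on the negated matrix; rectangular matrices
    yield min(rows, cols) pairs. Pairs are returned sorted by row index.
    """
    score = np.asarray(score, dtype=float)
    if score.size == 0:
        return []
    if score.ndim != 2:
        raise ValueError(f"score must be a 2-D matrix, got ndim={score.ndim}")
    if not np.all(np.isfinite(score)) or np.any(score < 0):
        raise ValueError("score entries must be finite and non-negative")
    rows, cols = scipy.optimize.linear_sum_assignment(-score)
    return sorted(zip(rows.tolist(), cols.tolist()))


def match_tracks(
    predicted: list[BoundingBox],
    detections: list[BoundingBox],
    iou_gate: float = 0.7,
    metric: str = "iou",
    nwd_params: NWDParams | None = None,
    pre_mask: bool = False,
) -> MatchResult:
    """Match predicted track boxes to detections by optimal IoU assignment.

    An assigned pair survives only if its score strictly exceeds
    ``iou_gate``; dissolved pairs fall back to unmatched on both sides.
    ``metric="nwd"`` swaps the IoU similarity for NWD (experimental).
    """
    if not (0.0 <= iou_gate < 1.0):
        raise ValueError(f"iou_gate must lie in [0, 1), got {iou_gate}")
    nt, nd = len(predicted), len(detections)
    if nt == 0 or nd == 0:
        return MatchResult([], list(range(nt)), list(range(nd)))

    if metric == "iou":
        score = iou_matrix(predicted, detections)
    elif metric == "nwd":
        p = nwd_params or NWDParams()
        score = np.array([[nwd(t, d, p) for d in detections] for t in predicted])
    else:
        raise ValueError(f"unknown metric {metric!r}")

    if pre_mask:
        masked = np.where(score > iou_gate, score, 0.0)
        pairs = solve_assignment(masked)
    else:
        pairs = solve_assignment(score)

    matches: list[tuple[int, int, float]] = []
    for r, c in pairs:
        s = float(score[r, c])
        if s > iou_gate:
            matches.append((r, c, s))
    matched_t = {r for r, _, _ in matches}
    matched_d = {c for _, c, _ in matches}
    return MatchResult(
        matches=matches,
        unmatched_tracks=[i for i in range(nt) if i not in matched_t],
        unmatched_detections=[j for j in range(nd) if j not in matched_d],
    )
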