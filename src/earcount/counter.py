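"""Baseline-crossing object counter over a stream of per-frame detections.

Each frame is processed in four steps — detect, match, count, update:

1. every live track is advanced one frame by the Kalman predict step;
2. predicted boxes are matched one-to-one to the frame's detections by
   optimal IoU assignment with a gate (default 0.7);
3. a matched track whose estimated center crossed the counting baseline
   between its previous and current position (in the configured direction)
   is counted, once and only once per identity;
4. matched tracks are measurement-updated, unmatched detections spawn new
   tracks with fresh sequential ids, and tracks unmatched for longer than
   ``max_age`` frames are deleted.

Counting at a fixed line near the bottom of the frame — rather than counting
every new identity — avoids double counts from identity switches and avoids
counting objects that appear only partially at the frame edge, where
detector boxes are unreliable. Crossing is only registered on matched
frames: a track coasting on prediction alone cannot be counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .assignment import match_tracks
from .detections import FrameDetections
from .geometry import BoundingBox
from .kalman import KFModel, KFState, kf_init, kf_predict, kf_update, state_box

__all__ = [
    "Track",
    "CounterConfig",
    "CountResult",
    "Tracker",
    "FrameOrderError",
    "run",
    "count_video",
]


class FrameOrderError(ValueError):
    """Detections arrived for a frame index that does not advance time."""


@dataclass
class Track:
    """One tracked object identity."""

    id: int
    state: KFState
    hits: int = 1
    time_since_update: int = 0
    counted: bool = False
    last_cy: float = 0.0  # posterior center y at the last matched frame
    history: list[tuple[int, BoundingBox]] = field(default_factory=list)


@dataclass(frozen=True)
class CounterConfig:
    """Tracker/counter parameters.

    ``baseline_y`` defaults to 90% of the frame height — near the bottom,
    where every swept object eventually passes, but clear of the edge strip
    where boxes are clipped. ``max_age`` (default 5 frames, ≈0.17 s at
    30 FPS) is how long a track may coast unmatched before it is deleted as
    disappeared: long enough to ride out typical detector dropout bursts,
    short enough that ghost tracks cannot shadow a neighbour. ``min_hits``
    gates counting on a minimum number of successful matches.

    A newborn track has no velocity estimate, so its one-frame-ahead
    prediction trails the object by one sweep step; at the sweep speed and
    object sizes of the acquisition geometry that first pair sits at
    IoU ≈ 0.6, below the 0.7 gate, and a freshly locked velocity carries the
    localisation noise of its first two observations. Tracks therefore serve
    a probation of ``confirm_hits`` matches (default 5 — the number of
    predict/update cycles the constant-velocity filter needs to lock its
    velocity) during which association is gated at ``tentative_iou_gate``
    (default 0.3, the classic online-tracking threshold). Confirmed tracks
    are gated strictly at ``iou_gate`` on consecutive-frame matches; a
    confirmed track that coasted on the previous frame is re-acquired at the
    relaxed gate, since its prediction has aged by at least one frame.
    """

    frame_size: tuple[int, int] = (768, 432)
    iou_gate: float = 0.7
    tentative_iou_gate: float = 0.3
    confirm_hits: int = 5
    baseline_y: float | None = None
    crossing_direction: str = "downward"  # downward | upward | either
    max_age: int = 5
    min_hits: int = 1

    def __post_init__(self) -> None:
        if self.crossing_direction not in ("downward", "upward", "either"):
            raise ValueError(f"bad crossing_direction {self.crossing_direction!r}")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.baseline_y is not None and not (
            0 <= self.baseline_y <= self.frame_size[1]
        ):
            raise ValueError(
                f"baseline_y={self.baseline_y} outside frame height {self.frame_size[1]}"
            )

    @property
    def baseline(self) -> float:
        if self.baseline_y is not None:
            return float(self.baseline_y)
        return 0.9 * self.frame_size[1]


@dataclass
class CountResult:
    """Final count plus full track provenance."""

    total: int
    counted_ids: set[int]
    per_frame_counts: list[tuple[int, int]]
    tracks: list[Track]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counted_ids": sorted(self.counted_ids),
            "per_frame_counts": [list(t) for t in self.per_frame_counts],
            "tracks": [
                {
                    "id": t.id,
                    "hits": t.hits,
                    "counted": t.counted,
                    "first_frame": t.history[0][0] if t.history else None,
                    "last_frame": t.history[-1][0] if t.history else None,
                }
                for t in self.tracks
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _crossed(prev_y: float, cur_y: float, baseline: float, direction: str) -> bool:
    down = prev_y < baseline <= cur_y
    up = prev_y > baseline >= cur_y
    if direction == "downward":
        return down
    if direction == "upward":
        return up
    return down or up


class Tracker:
    """Stateful per-frame counter; feed frames in ascending order via
    :meth:`step` and read the result from :meth:`result`."""

    def __init__(self, cfg: CounterConfig | None = None, model: KFModel | None = None):
        self.cfg = cfg or CounterConfig()
        self.model = model or KFModel.constant_velocity()
        self.tracks: list[Track] = []
        self.counted_ids: set[int] = set()
        self.per_frame_counts: list[tuple[int, int]] = []
        self.finished_tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None
        # global scene flow (px/frame): the camera sweep moves every object
        # by the same vector, estimated from the median nearest-neighbour
        # displacement between consecutive detection sets (MAD-gated against
        # dropout-induced mispairings, exponentially smoothed over frames
        # since the sweep speed is constant) and used to seed the velocity
        # of newborn tracks (ego-motion compensation)
        self._flow = np.zeros(2)
        self._flow_initialized = False
        self._prev_centers: np.ndarray | None = None

    def _update_flow(self, detections: FrameDetections, frame_delta: int) -> None:
        centers = np.array([[b.cx, b.cy] for b in detections.boxes]).reshape(-1, 2)
        prev = self._prev_centers
        self._prev_centers = centers if centers.size else None
        if prev is None or not centers.size:
            return
        disp = centers[:, None, :] - prev[None, :, :]
        nearest = np.argmin(np.einsum("ijk,ijk->ij", disp, disp), axis=1)
        d = disp[np.arange(len(centers)), nearest]
        med = np.median(d, axis=0)
        # discard mispaired displacements (an object whose true partner was
        # dropped pairs with a far neighbour) before re-estimating
        mad = np.median(np.abs(d - med), axis=0)
        keep = np.all(np.abs(d - med) <= np.maximum(3.0 * mad, 2.0), axis=1)
        if np.any(keep):
            med = np.median(d[keep], axis=0)
        obs = med / max(frame_delta, 1)
        # velocities of locked-on filters average many frames and beat the
        # raw two-frame displacement estimate whenever enough are available
        vels = np.array(
            [
                t.state.x[4:6]
                for t in self.tracks
                if t.hits >= self.cfg.confirm_hits and t.time_since_update == 0
            ]
        ).reshape(-1, 2)
        if len(vels) >= 3:
            obs = np.median(vels, axis=0)
        if not self._flow_initialized:
            self._flow = obs
            self._flow_initialized = True
        else:
            self._flow = 0.7 * self._flow + 0.3 * obs

    def step(self, detections: FrameDetections) -> list[int]:
        """Process one frame; returns the ids newly counted this frame."""
        frame = detections.frame
        if self._last_frame is not None and frame <= self._last_frame:
            raise FrameOrderError(
                f"frame {frame} does not advance past {self._last_frame}"
            )
        delta = frame - self._last_frame if self._last_frame is not None else 1
        self._last_frame = frame
        cfg, model = self.cfg, self.model
        self._update_flow(detections, delta)

        # 1. predict all live tracks one frame forward
        for t in self.tracks:
            t.state = kf_predict(t.state, model)
        predicted = [state_box(t.state) for t in self.tracks]
        valid_idx = [i for i, b in enumerate(predicted) if b is not None]

        # 2. optimal IoU assignment; gate at the looser tentative threshold,
        # then dissolve pairs of velocity-locked tracks below the strict gate
        low_gate = min(cfg.tentative_iou_gate, cfg.iou_gate)
        res = match_tracks(
            [predicted[i] for i in valid_idx],
            list(detections.boxes),
            iou_gate=low_gate,
        )

        newly_counted: list[int] = []
        matched_tracks: set[int] = set()
        for vi, dj, score in res.matches:
            ti = valid_idx[vi]
            t = self.tracks[ti]
            strict = t.hits >= cfg.confirm_hits and t.time_since_update == 0
            if strict and score <= cfg.iou_gate:
                # confirmed consecutive-frame pair below the strict gate:
                # dissolved. The detection is still explained by this track
                # (it overlapped above the tentative gate), so it must not
                # seed a duplicate identity; the track coasts this frame and
                # may re-acquire the object at the relaxed gate next frame.
                continue
            matched_tracks.add(ti)
            prev_cy = t.last_cy
            t.state = kf_update(t.state, detections.boxes[dj], model)
            t.hits += 1
            t.time_since_update = 0
            cur_cy = float(t.state.x[1])
            # 3. count on baseline crossing of the posterior center
            if (
                not t.counted
                and t.hits >= cfg.min_hits
                and _crossed(prev_cy, cur_cy, cfg.baseline, cfg.crossing_direction)
            ):
                t.counted = True
                self.counted_ids.add(t.id)
                newly_counted.append(t.id)
            t.last_cy = cur_cy
            posterior = state_box(t.state, detections.boxes[dj].conf)
            if posterior is not None:
                t.history.append((frame, posterior))

        # 4a. age unmatched tracks (including ones with degenerate predictions)
        for i, t in enumerate(self.tracks):
            if i not in matched_tracks:
                t.time_since_update += 1

        # 4b. spawn tracks from unmatched detections
        for dj in res.unmatched_detections:
            z = detections.boxes[dj]
            t = Track(
                id=self._next_id,
                state=kf_init(z, model, velocity=self._flow),
                last_cy=z.cy,
                history=[(frame, z)],
            )
            self._next_id += 1
            self.tracks.append(t)

        # 4c. delete stale tracks (ids are never reused)
        survivors, dead = [], []
        for t in self.tracks:
            (survivors if t.time_since_update <= cfg.max_age else dead).append(t)
        self.tracks = survivors
        self.finished_tracks.extend(dead)

        self.per_frame_counts.append((frame, len(self.counted_ids)))
        return newly_counted

    def result(self) -> CountResult:
        all_tracks = self.finished_tracks + self.tracks
        all_tracks.sort(key=lambda t: t.id)
        return CountResult(
            total=len(self.counted_ids),
            counted_ids=set(self.counted_ids),
            per_frame_counts=list(self.per_frame_counts),
            tracks=all_tracks,
        )


def run(
    detection_stream: Iterable[FrameDetections],
    cfg: CounterConfig | None = None,
    model: KFModel | None = None,
) -> CountResult:
    """Fold the per-frame counter over an ascending detection stream."""
    tracker = Tracker(cfg, model)
    for dets in detection_stream:
        tracker.step(dets)
    return tracker.result()


def count_video(
    frames: Iterable,
    detector: Callable[[object, int], Sequence[BoundingBox] | FrameDetections],
    cfg: CounterConfig | None = None,
    model: KFModel | None = None,
) -> CountResult:
    """Count over a frame source with an injected detector.

    ``detector(image, frame_index)`` returns the detections of one frame;
    any per-frame detector (including a neural one) can be plugged in.
    Detector failures are re-raised with the offending frame index.
    """

    def stream() -> Iterator[FrameDetections]:
        for idx, image in enumerate(frames):
            try:
                out = detector(image, idx)
            except Exception as exc:
                raise RuntimeError(f"detector failed on frame {idx}: {exc}") from exc
            if isinstance(out, FrameDetections):
                if out.frame != idx:
                    raise FrameOrderError(
                        f"detector returned frame {out.frame} for frame {idx}"
                    )
                yield out
            else:
                yield FrameDetections(frame=idx, boxes=tuple(out))

    return run(stream(), cfg, model)
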