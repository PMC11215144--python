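"""Baseline-crossing counter: lifecycle, counting rules, robustness."""

import numpy as np
import pytest

from earcount import (
    BoundingBox,
    CounterConfig,
    FrameDetections,
    KFModel,
    SceneConfig,
    Tracker,
    corrupt_detections,
    count_video,
    generate_scene,
    run,
)
from earcount.counter import FrameOrderError


def frames_from_tracks(trajectories, n_frames):
    """Build a detection stream from {start_frame: [(cx, cy, w, h) per frame]}."""
    out = []
    for t in range(n_frames):
        boxes = []
        for start, boxes_per_frame in trajectories:
            k = t - start
            if 0 <= k < len(boxes_per_frame) and boxes_per_frame[k] is not None:
                boxes.append(BoundingBox(*boxes_per_frame[k]))
        out.append(FrameDetections(frame=t, boxes=tuple(boxes)))
    return out


def falling_object(cx, y_start, step, n, w=8.0, h=16.0):
    return [(cx, y_start + k * step, w, h) for k in range(n)]


CFG = CounterConfig(frame_size=(100, 100), baseline_y=80.0)


class TestStep:
    def test_first_frame_spawns_sequential_ids(self):
        tr = Tracker(CFG)
        tr.step(FrameDetections(0, [BoundingBox(10, 10, 4, 4),
                                    BoundingBox(30, 10, 4, 4),
                                    BoundingBox(50, 10, 4, 4)]))
        assert sorted(t.id for t in tr.tracks) == [1, 2, 3]
        assert not any(t.counted for t in tr.tracks)

    def test_baseline_straddle_counts(self):
        tr = Tracker(CFG)
        tr.step(FrameDetections(0, [BoundingBox(50, 78, 8, 16)]))
        newly = tr.step(FrameDetections(1, [BoundingBox(50, 82, 8, 16)]))
        assert newly == [1]
        assert tr.result().total == 1

    def test_counted_only_once_while_hovering(self):
        # the object sits on the line for several frames after crossing
        stream = frames_from_tracks(
            [(0, [(50, 78, 8, 16), (50, 81, 8, 16), (50, 80.5, 8, 16),
                  (50, 81.5, 8, 16), (50, 83, 8, 16)])], 5)
        res = run(stream, CFG)
        assert res.total == 1
        assert res.counted_ids == {1}

    def test_track_removed_after_max_age_never_counted(self):
        cfg = CounterConfig(frame_size=(100, 100), baseline_y=80.0, max_age=2)
        tr = Tracker(cfg)
        tr.step(FrameDetections(0, [BoundingBox(50, 10, 8, 16)]))
        for t in range(1, 5):
            tr.step(FrameDetections(t, []))
        assert tr.tracks == []
        res = tr.result()
        assert res.total == 0 and len(res.tracks) == 1

    def test_frame_regression_rejected(self):
        tr = Tracker(CFG)
        tr.step(FrameDetections(3, []))
        with pytest.raises(FrameOrderError):
            tr.step(FrameDetections(3, []))
        with pytest.raises(FrameOrderError):
            tr.step(FrameDetections(1, []))


class TestRun:
    def test_empty_stream(self):
        res = run([], CFG)
        assert res.total == 0 and res.per_frame_counts == []

    def test_single_object_through_baseline(self):
        stream = frames_from_tracks([(0, falling_object(50, 10, 4, 25))], 25)
        res = run(stream, CFG)
        assert res.total == 1
        assert res.counted_ids == {1}

    def test_object_stopping_above_baseline_not_counted(self):
        stream = frames_from_tracks([(0, falling_object(50, 10, 4, 15))], 15)
        # final y = 10 + 14*4 = 66 < baseline 80
        assert run(stream, CFG).total == 0

    def test_cumulative_counts_monotone(self):
        cfg = SceneConfig(n_objects=40, n_frames=80, seed=11)
        truth = generate_scene(cfg)
        res = run(corrupt_detections(truth),
                  CounterConfig(frame_size=cfg.frame_size, baseline_y=truth.baseline_y))
        counts = [c for _, c in res.per_frame_counts]
        assert counts == sorted(counts)
        assert res.total == counts[-1] == len(res.counted_ids)

    def test_counted_once_under_random_streams(self, rng):
        """No identity is ever counted twice, whatever the stream."""
        for _ in range(10):
            stream = []
            for t in range(40):
                boxes = [
                    BoundingBox(
                        float(rng.uniform(0, 100)), float(rng.uniform(0, 100)),
                        float(rng.uniform(3, 15)), float(rng.uniform(3, 15)))
                    for _ in range(rng.integers(0, 8))
                ]
                stream.append(FrameDetections(frame=t, boxes=tuple(boxes)))
            tr = Tracker(CFG)
            events = []
            for fd in stream:
                events.extend(tr.step(fd))
            assert len(events) == len(set(events))
            assert tr.result().total == len(events)

    def test_noiseless_scene_recovered_exactly(self):
        for seed in (0, 1, 2):
            cfg = SceneConfig(n_objects=50, n_frames=100, seed=seed)
            truth = generate_scene(cfg)
            res = run(corrupt_detections(truth),
                      CounterConfig(frame_size=cfg.frame_size, baseline_y=truth.baseline_y))
            assert res.total == truth.expected_count

    def test_deterministic(self):
        cfg = SceneConfig(n_objects=30, n_frames=60, seed=7, detect_prob=0.8,
                          jitter_sigma=1.0)
        truth = generate_scene(cfg)
        dets = corrupt_detections(truth)
        ccfg = CounterConfig(frame_size=cfg.frame_size, baseline_y=truth.baseline_y)
        assert run(dets, ccfg).total == run(dets, ccfg).total


class TestCountVideo:
    def test_adapter_equivalence_with_run(self):
        cfg = SceneConfig(n_objects=25, n_frames=50, seed=5)
        truth = generate_scene(cfg)
        dets = corrupt_detections(truth)
        ccfg = CounterConfig(frame_size=cfg.frame_size, baseline_y=truth.baseline_y)

        def replay_detector(image, idx):
            return dets[idx].boxes

        direct = run(dets, ccfg)
        adapted = count_video(range(len(dets)), replay_detector, ccfg)
        assert adapted.total == direct.total
        assert adapted.counted_ids == direct.counted_ids

    def test_seeded_dropout_detector_deterministic(self):
        cfg = SceneConfig(n_objects=25, n_frames=50, seed=5)
        truth = generate_scene(cfg)
        dets = corrupt_detections(truth)
        ccfg = CounterConfig(frame_size=cfg.frame_size, baseline_y=truth.baseline_y)

        def dropout_detector_factory():
            local = np.random.default_rng(99)
            def det(image, idx):
                return [b for b in dets[idx].boxes if local.uniform() > 0.2]
            return det

        a = count_video(range(len(dets)), dropout_detector_factory(), ccfg)
        b = count_video(range(len(dets)), dropout_detector_factory(), ccfg)
        assert a.total == b.total

    def test_zero_frames(self):
        assert count_video([], lambda im, i: [], CFG).total == 0

    def test_detector_failure_reports_frame(self):
        def bad(image, idx):
            if idx == 2:
                raise RuntimeError("boom")
            return []

        with pytest.raises(RuntimeError, match="frame 2"):
            count_video(range(5), bad, CFG)


def test_result_json_round_trip():
    import json

    stream = frames_from_tracks([(0, falling_object(50, 70, 4, 6))], 6)
    res = run(stream, CFG)
    doc = json.loads(res.to_json())
    assert doc["total"] == res.total
    assert doc["counted_ids"] == sorted(res.counted_ids)
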