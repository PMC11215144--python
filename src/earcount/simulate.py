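"""Synthetic UAV-sweep scene generator with ground truth and a noisy detector.

The simulator emulates a nadir camera sweeping a planar crop canopy at
constant speed: objects (wheat ears) are static points on a long world
strip, and the camera window advances a fixed number of pixels per frame,
so in image coordinates every object drifts downward at ``sweep_speed``
px/frame, enters at the top edge and exits at the bottom. Optional
sinusoidal sway (wind) displaces each object's center with a per-object
phase.

Default scale is a 5× downscale of the acquisition geometry: 3840×2160 @
30 FPS at 0.5 m/s, 4 m above the canopy. With the pixel density fixed at
1200 px/m at full resolution, 0.5 m/s is 20 px/frame full-res, i.e. 4
px/frame at the default 768×432 frame; full-res object sizes of 30×80 to
60×100 px become 6×16 to 12×20 px. The default object count is drawn
uniformly from the 300–700 range reported per video, scaled by the
frame-area ratio.

``corrupt_detections`` turns the ground truth into detector output: each
true box survives with probability ``detect_prob`` (reduced for boxes
clipped at the frame edge), kept boxes get Gaussian jitter on center and
log-size, and spurious boxes arrive as a Poisson stream per frame. One
scene seed feeds independent sub-generators for placement, sway, dropout,
jitter and false positives, so switching one noise source on or off leaves
the draws of the others unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detections import FrameDetections
from .geometry import BoundingBox

__all__ = [
    "FULL_FRAME",
    "PX_PER_M_FULL",
    "SceneConfig",
    "SceneObject",
    "TruthBox",
    "SceneTruth",
    "generate_scene",
    "corrupt_detections",
    "truth_detections",
]

FULL_FRAME = (3840, 2160)  # acquisition resolution, px
PX_PER_M_FULL = 1200.0  # pixel density at full resolution, px/m


@dataclass(frozen=True)
class SceneConfig:
    """Scene and detector-noise parameters (pixels, frames).

    ``n_objects=None`` draws uniformly from [300, 700] scaled by the ratio
    of the frame area to the full 3840×2160 acquisition frame.
    """

    frame_size: tuple[int, int] = (768, 432)  # (width, height)
    n_frames: int = 150
    sweep_speed: float = 4.0  # px/frame; 0.5 m/s @ 30 FPS, 1200 px/m, /5 scale
    n_objects: int | None = None
    object_w_range: tuple[float, float] = (6.0, 12.0)
    object_h_range: tuple[float, float] = (16.0, 20.0)
    detect_prob: float = 1.0
    jitter_sigma: float = 0.0  # px, on centers; sizes jittered ~ the same in px
    false_pos_rate: float = 0.0  # expected spurious boxes per frame
    sway_amp: float = 0.0  # px
    sway_period: float = 30.0  # frames
    partial_detect_exponent: float = 2.0  # edge-clipped boxes: p_keep = detect_prob**exp
    baseline_frac: float = 0.9  # counting line as a fraction of frame height
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ValueError("detect_prob must lie in [0, 1]")
        for name in ("object_w_range", "object_h_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.n_frames < 1 or self.sweep_speed < 0:
            raise ValueError("need n_frames >= 1 and sweep_speed >= 0")

    @property
    def baseline_y(self) -> float:
        return self.baseline_frac * self.frame_size[1]


@dataclass(frozen=True)
class SceneObject:
    """A static object on the world strip (positions in frame-0 coordinates)."""

    id: int
    x: float
    y0: float  # image y at frame 0; frame-t position is y0 + t * sweep_speed
    w: float
    h: float
    phase_x: float = 0.0
    phase_y: float = 0.0


@dataclass(frozen=True)
class TruthBox:
    """One ground-truth box of one frame; ``partial`` marks edge clipping."""

    object_id: int
    box: BoundingBox
    partial: bool


@dataclass(frozen=True)
class SceneTruth:
    """Simulator output: object registry, per-frame boxes, crossing count."""

    config: SceneConfig
    objects: tuple[SceneObject, ...]
    frames: tuple[tuple[TruthBox, ...], ...]
    baseline_y: float
    crossing_ids: frozenset[int]

    @property
    def expected_count(self) -> int:
        return len(self.crossing_ids)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("placement", "sway", "dropout", "jitter", "falsepos")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _object_center(obj: SceneObject, t: int, cfg: SceneConfig) -> tuple[float, float]:
    x, y = obj.x, obj.y0 + t * cfg.sweep_speed
    if cfg.sway_amp > 0:
        arg = 2.0 * np.pi * t / cfg.sway_period
        x += cfg.sway_amp * np.sin(arg + obj.phase_x)
        y += cfg.sway_amp * np.sin(arg + obj.phase_y)
    return x, y


def generate_scene(cfg: SceneConfig) -> SceneTruth:
    """Sample a scene and roll the camera over it.

    Objects are uniform over the swept strip; per frame, every object whose
    box overlaps the window yields a ground-truth box, clipped to the frame
    and flagged partial when clipping occurred. Deterministic given
    ``cfg.seed``.
    """
    rng = _rngs(cfg.seed)
    W, H = cfg.frame_size
    place = rng["placement"]

    if cfg.n_objects is None:
        area_ratio = (W * H) / (FULL_FRAME[0] * FULL_FRAME[1])
        n = max(1, int(round(place.uniform(300, 700) * area_ratio)))
    else:
        n = int(cfg.n_objects)

    xs = place.uniform(0, W, size=n)
    y0s = place.uniform(-cfg.n_frames * cfg.sweep_speed, H, size=n)
    ws = place.uniform(*cfg.object_w_range, size=n)
    hs = place.uniform(*cfg.object_h_range, size=n)
    phases = rng["sway"].uniform(0, 2 * np.pi, size=(n, 2))
    objects = tuple(
        SceneObject(
            id=i + 1, x=float(xs[i]), y0=float(y0s[i]),
            w=float(ws[i]), h=float(hs[i]),
            phase_x=float(phases[i, 0]), phase_y=float(phases[i, 1]),
        )
        for i in range(n)
    )

    frames: list[tuple[TruthBox, ...]] = []
    for t in range(cfg.n_frames):
        entries: list[TruthBox] = []
        for obj in objects:
            cx, cy = _object_center(obj, t, cfg)
            x1, y1 = cx - obj.w / 2, cy - obj.h / 2
            x2, y2 = cx + obj.w / 2, cy + obj.h / 2
            cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
            cx2, cy2 = min(x2, float(W)), min(y2, float(H))
            if cx2 - cx1 <= 0 or cy2 - cy1 <= 0:
                continue
            partial = (cx1, cy1, cx2, cy2) != (x1, y1, x2, y2)
            entries.append(
                TruthBox(obj.id, BoundingBox.from_corners(cx1, cy1, cx2, cy2), partial)
            )
        frames.append(tuple(entries))

    baseline = cfg.baseline_y
    crossing: set[int] = set()
    for obj in objects:
        prev = _object_center(obj, 0, cfg)[1]
        for t in range(1, cfg.n_frames):
            cur = _object_center(obj, t, cfg)[1]
            if prev < baseline <= cur:
                crossing.add(obj.id)
                break
            prev = cur

    return SceneTruth(
        config=cfg,
        objects=objects,
        frames=tuple(frames),
        baseline_y=baseline,
        crossing_ids=frozenset(crossing),
    )


def truth_detections(truth: SceneTruth) -> list[FrameDetections]:
    """The ground truth replayed as a perfect detector (identity channel)."""
    return [
        FrameDetections(frame=t, boxes=tuple(tb.box for tb in entries))
        for t, entries in enumerate(truth.frames)
    ]


def corrupt_detections(
    truth: SceneTruth, cfg: SceneConfig | None = None
) -> list[FrameDetections]:
    """Pass the ground truth through a noisy-detector channel.

    With ``detect_prob=1``, ``jitter_sigma=0`` and ``false_pos_rate=0`` the
    output equals the truth boxes exactly. Size jitter is multiplicative on
    log-size with scale ``jitter_sigma / size``, i.e. roughly
    ``jitter_sigma`` pixels of size noise. Deterministic given the seed.
    """
    cfg = cfg or truth.config
    rng = _rngs(cfg.seed)
    drop, jit, fprng = rng["dropout"], rng["jitter"], rng["falsepos"]
    W, H = cfg.frame_size
    w_lo, w_hi = cfg.object_w_range
    h_lo, h_hi = cfg.object_h_range

    out: list[FrameDetections] = []
    for t, entries in enumerate(truth.frames):
        boxes: list[BoundingBox] = []
        for tb in entries:
            p = cfg.detect_prob ** (cfg.partial_detect_exponent if tb.partial else 1.0)
            if drop.uniform() >= p:
                continue
            b = tb.box
            if cfg.jitter_sigma > 0:
                dx, dy = jit.normal(0.0, cfg.jitter_sigma, size=2)
                # ~jitter_sigma px of size noise, capped at 50% relative for
                # slivers clipped to sub-pixel width at the frame edge
                lw = np.log(b.w) + jit.normal(0.0, min(cfg.jitter_sigma / b.w, 0.5))
                lh = np.log(b.h) + jit.normal(0.0, min(cfg.jitter_sigma / b.h, 0.5))
                b = BoundingBox(
                    b.cx + dx, b.cy + dy,
                    float(np.exp(lw)), float(np.exp(lh)), conf=b.conf,
                )
            boxes.append(b)
        if cfg.false_pos_rate > 0:
            for _ in range(fprng.poisson(cfg.false_pos_rate)):
                boxes.append(
                    BoundingBox(
                        cx=float(fprng.uniform(0, W)),
                        cy=float(fprng.uniform(0, H)),
                        w=float(fprng.uniform(w_lo, w_hi)),
                        h=float(fprng.uniform(h_lo, h_hi)),
                        conf=float(fprng.uniform(0.1, 0.5)),
                    )
                )
        out.append(FrameDetections(frame=t, boxes=tuple(boxes)))
    return out
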