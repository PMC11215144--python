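"""Per-frame detection container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import BoundingBox

__all__ = ["FrameDetections"]


@dataclass(frozen=True)
class FrameDetections:
    """All detections of one video frame. Frame indices are 0-based."""

    frame: int
    boxes: tuple[BoundingBox, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")

    def __len__(self) -> int:
        return len(self.boxes)
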