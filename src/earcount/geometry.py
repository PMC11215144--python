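"""Box geometry: IoU, Gaussian box models, Wasserstein distance, NWD.

Axis-aligned boxes live in continuous pixel coordinates with the origin at
the top-left corner, x increasing rightward and y increasing downward (the
image convention). A box is stored in center form ``(cx, cy, w, h)``.

For tiny objects the IoU between a prediction and the ground truth is often
exactly zero (no overlap) or saturated (full containment), which makes it a
poor similarity measure. The Normalized Gaussian Wasserstein Distance (NWD)
instead models each box as a 2-D Gaussian — mean at the box center,
diagonal covariance ``diag(w²/4, h²/4)`` — and measures the 2-Wasserstein
distance between the two Gaussians, mapped to a (0, 1] similarity through
``exp(-d / C)``. Unlike IoU, NWD varies smoothly with center distance even
for disjoint boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "InvalidBoxError",
    "BoundingBox",
    "GaussianBox",
    "NWDParams",
    "iou",
    "iou_matrix",
    "box_to_gaussian",
    "gaussian_to_box",
    "wasserstein_sq",
    "nwd",
    "nwd_loss",
]


class InvalidBoxError(ValueError):
    """A bounding box with non-positive width or height."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in center form.

    Parameters
    ----------
    cx, cy : float
        Center coordinates in pixels.
    w, h : float
        Width and height in pixels; must be strictly positive.
    conf : float, optional
        Detection confidence in [0, 1]; defaults to 1.
    """

    cx: float
    cy: float
    w: float
    h: float
    conf: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(
                f"box width and height must be positive, got w={self.w}, h={self.h}"
            )
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.conf}")

    # corner form (x1, y1) top-left, (x2, y2) bottom-right, half-open
    @property
    def x1(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    @classmethod
    def from_corners(
        cls, x1: float, y1: float, x2: float, y2: float, conf: float = 1.0
    ) -> "BoundingBox":
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1, conf)

    @classmethod
    def from_xywh(
        cls, x: float, y: float, w: float, h: float, conf: float = 1.0
    ) -> "BoundingBox":
        """Build from top-left corner + size (the MOT file convention)."""
        return cls(x + w / 2.0, y + h / 2.0, w, h, conf)


@dataclass(frozen=True)
class GaussianBox:
    """2-D Gaussian model of a box: mean vector and covariance matrix."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float).reshape(2)
        sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if not np.allclose(sigma, sigma.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(sigma) <= 0):
            raise ValueError("covariance must be positive definite")

    @property
    def is_diagonal(self) -> bool:
        return self.sigma[0, 1] == 0.0 and self.sigma[1, 0] == 0.0


@dataclass(frozen=True)
class NWDParams:
    """Parameters of the NWD similarity.

    ``C`` is the dataset-scale normalization constant (pixels); it should be
    on the order of a typical object extent for the similarity to
    discriminate. ``use_sqrt`` selects the exponent: the 2-Wasserstein
    *distance* (default) or its square.
    """

    C: float = 12.8
    use_sqrt: bool = True

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, symmetric."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(boxes_a: list[BoundingBox], boxes_b: list[BoundingBox]) -> np.ndarray:
    """Pairwise IoU, shape (len(boxes_a), len(boxes_b)). Vectorized."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    A = np.array([b.corners() for b in boxes_a])  # (n, 4)
    B = np.array([b.corners() for b in boxes_b])  # (m, 4)
    ix = np.minimum(A[:, None, 2], B[None, :, 2]) - np.maximum(A[:, None, 0], B[None, :, 0])
    iy = np.minimum(A[:, None, 3], B[None, :, 3]) - np.maximum(A[:, None, 1], B[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (A[:, 2] - A[:, 0]) * (A[:, 3] - A[:, 1])
    area_b = (B[:, 2] - B[:, 0]) * (B[:, 3] - B[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def box_to_gaussian(b: BoundingBox) -> GaussianBox:
    """Model a box as N(mu, Sigma) with mu=(cx,cy), Sigma=diag(w²/4, h²/4)."""
    return GaussianBox(
        mu=np.array([b.cx, b.cy], dtype=float),
        sigma=np.diag([b.w**2 / 4.0, b.h**2 / 4.0]),
    )


def gaussian_to_box(g: GaussianBox, conf: float = 1.0) -> BoundingBox:
    """Inverse of :func:`box_to_gaussian` for diagonal covariances."""
    if not g.is_diagonal:
        raise ValueError("only diagonal-covariance Gaussians map back to boxes")
    w = 2.0 * float(np.sqrt(g.sigma[0, 0]))
    h = 2.0 * float(np.sqrt(g.sigma[1, 1]))
    return BoundingBox(float(g.mu[0]), float(g.mu[1]), w, h, conf)


def wasserstein_sq(g1: GaussianBox, g2: GaussianBox, method: str = "auto") -> float:
    """Squared 2-Wasserstein distance between two 2-D Gaussians, in pixels².

    W₂² = ‖m₁−m₂‖² + Tr(Σ₁+Σ₂−2(Σ₂^{1/2} Σ₁ Σ₂^{1/2})^{1/2}).

    For the diagonal covariances produced by :func:`box_to_gaussian` the trace
    term collapses to ``((w1−w2)/2)² + ((h1−h2)/2)²``, which the ``"closed"``
    method uses; ``"matrix"`` evaluates the general matrix-square-root form;
    ``"auto"`` picks the closed form whenever both covariances are diagonal.
    """
    if method not in ("auto", "closed", "matrix"):
        raise ValueError(f"unknown method {method!r}")
    diff = float(np.sum((g1.mu - g2.mu) ** 2))
    diagonal = g1.is_diagonal and g2.is_diagonal
    if method == "closed" and not diagonal:
        raise ValueError("closed form requires diagonal covariances")
    if method == "matrix" or not diagonal:
        root2 = scipy.linalg.sqrtm(g2.sigma)
        inner = scipy.linalg.sqrtm(root2 @ g1.sigma @ root2)
        trace = float(np.trace(g1.sigma + g2.sigma - 2.0 * np.real(inner)))
    else:
        s1 = np.sqrt(np.diag(g1.sigma))
        s2 = np.sqrt(np.diag(g2.sigma))
        trace = float(np.sum((s1 - s2) ** 2))
    return max(diff + trace, 0.0)


def _wasserstein_sq_boxes(a: BoundingBox, b: BoundingBox) -> float:
    # closed form straight from center-form boxes; avoids building Gaussians
    return (
        (a.cx - b.cx) ** 2
        + (a.cy - b.cy) ** 2
        + ((a.w - b.w) / 2.0) ** 2
        + ((a.h - b.h) / 2.0) ** 2
    )


def nwd(a: BoundingBox, b: BoundingBox, p: NWDParams = NWDParams()) -> float:
    """NWD similarity exp(−d/C) ∈ (0, 1]; 1 iff the boxes are identical.

    ``d`` is the 2-Wasserstein distance when ``p.use_sqrt`` (default), else
    its square.
    """
    w2 = _wasserstein_sq_boxes(a, b)
    d = float(np.sqrt(w2)) if p.use_sqrt else w2
    return float(np.exp(-d / p.C))


def nwd_loss(pred: BoundingBox, truth: BoundingBox, p: NWDParams = NWDParams()) -> float:
    """1 − NWD ∈ [0, 1): zero iff the boxes coincide, and — unlike an
    IoU loss — still informative (finite, non-saturated) for disjoint pairs."""
    return 1.0 - nwd(pred, truth, p)
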