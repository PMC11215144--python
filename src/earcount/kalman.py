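"""Constant-velocity Kalman filter over bounding-box state.

The state is the 8-vector ``(cx, cy, w, h, vcx, vcy, vw, vh)`` — box center,
box size, and their per-frame velocities — observed through the first four
components. With dt = 1 frame the transition matrix is ``[[I4, I4], [0, I4]]``
and the observation matrix ``[I4 | 0]``: positions and sizes drift at their
current velocity, velocities persist. Process noise Q absorbs the model error
(swaying plants, imperfect camera motion); observation noise R absorbs
detector localisation jitter.

predict:  x⁻ = F x (+ B u),  P⁻ = F P Fᵀ + Q
update:   K  = P⁻ Hᵀ (H P⁻ Hᵀ + R)⁻¹
          x  = x⁻ + K (z − H x⁻),  P = (I − K H) P⁻  (symmetrised)

Defaults (all configurable) are chosen so a sweep at a few pixels/frame is
tracked well within one object width: Q = diag(1e-2 on positions/sizes,
1e-4 on velocities), R = I px², initial P = diag(10 on positions, 1000 on
velocities) — a vague prior on velocity so the first few updates lock on
quickly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoundingBox

__all__ = ["KFModel", "KFState", "kf_init", "kf_predict", "kf_update", "state_box"]


@dataclass(frozen=True)
class KFModel:
    """Matrices of a linear-Gaussian state-space model.

    F : (8, 8) state transition; H : (4, 8) observation; Q, R process and
    observation noise covariances; optional control pair (B, u). ``p_pos`` /
    ``p_vel`` seed the initial state covariance.
    """

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    B: np.ndarray | None = None
    u: np.ndarray | None = None
    p_pos: float = 10.0
    p_vel: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("F", "H", "Q", "R"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name, m in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(m) < -1e-12):
                raise ValueError(f"{name} must be positive semi-definite")

    @classmethod
    def constant_velocity(
        cls,
        dt: float = 1.0,
        q_pos: float = 1e-2,
        q_vel: float = 1e-4,
        r: float = 1.0,
        p_pos: float = 10.0,
        p_vel: float = 1000.0,
    ) -> "KFModel":
        """Default box tracker: 8-D constant-velocity model, dt in frames."""
        eye4 = np.eye(4)
        F = np.block([[eye4, dt * eye4], [np.zeros((4, 4)), eye4]])
        H = np.hstack([eye4, np.zeros((4, 4))])
        Q = np.diag([q_pos] * 4 + [q_vel] * 4)
        R = r * eye4
        return cls(F=F, H=H, Q=Q, R=R, p_pos=p_pos, p_vel=p_vel)


@dataclass(frozen=True)
class KFState:
    """Filter state: mean vector x and covariance P (symmetric PSD)."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float).reshape(-1))
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float))


def _box_to_measurement(z: BoundingBox | np.ndarray) -> np.ndarray:
    if isinstance(z, BoundingBox):
        return np.array([z.cx, z.cy, z.w, z.h], dtype=float)
    return np.asarray(z, dtype=float).reshape(-1)


def kf_init(
    z: BoundingBox, model: KFModel, velocity: np.ndarray | None = None
) -> KFState:
    """Start a track at a detection: vague velocity prior, zero velocity
    unless an initial velocity estimate (e.g. global scene flow) is given."""
    n = model.F.shape[0]
    m = model.H.shape[0]
    x = np.zeros(n)
    x[:m] = _box_to_measurement(z)
    if velocity is not None:
        v = np.asarray(velocity, dtype=float).reshape(-1)
        x[m : m + v.size] = v
    P = np.diag([model.p_pos] * m + [model.p_vel] * (n - m))
    return KFState(x=x, P=P)


def kf_predict(s: KFState, model: KFModel) -> KFState:
    """Time update: propagate the mean through F and the covariance as
    F P Fᵀ + Q, with the optional control term B u added to the mean."""
    x = model.F @ s.x
    if model.B is not None and model.u is not None:
        x = x + np.asarray(model.B, dtype=float) @ np.asarray(model.u, dtype=float)
    P = model.F @ s.P @ model.F.T + model.Q
    return KFState(x=x, P=P)


def kf_update(s: KFState, z: BoundingBox | np.ndarray, model: KFModel) -> KFState:
    """Measurement update with Kalman gain K = P⁻Hᵀ(HP⁻Hᵀ+R)⁻¹.

    The posterior covariance is symmetrised to keep it PSD under roundoff.
    Raises a numerical error if the innovation covariance is singular.
    """
    zv = _box_to_measurement(z)
    H = model.H
    innov = zv - H @ s.x
    S = H @ s.P @ H.T + model.R
    try:
        K = np.linalg.solve(S.T, (s.P @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance (cond issue): S diag = {np.diag(S)}"
        ) from exc
    x = s.x + K @ innov
    P = (np.eye(s.P.shape[0]) - K @ H) @ s.P
    P = (P + P.T) / 2.0
    return KFState(x=x, P=P)


def state_box(s: KFState, conf: float = 1.0) -> BoundingBox | None:
    """The box described by the state mean, or None if the predicted size
    has collapsed to w <= 0 or h <= 0 (such a state is unusable for
    matching and the track should sit this frame out)."""
    cx, cy, w, h = s.x[:4]
    if w <= 0 or h <= 0:
        return None
    return BoundingBox(float(cx), float(cy), float(w), float(h), conf)
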