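"""Space-to-depth rearrangement of feature maps, and its inverse.

``space_to_depth`` moves each ``scale × scale`` spatial block of a
``(S_rows, S_cols, C)`` array into the channel dimension, producing a
``(S_rows/scale, S_cols/scale, C·scale²)`` array. It is a pure permutation:
no value is dropped or combined, so downsampling this way (as in SPDConv)
keeps all the fine-grained information that strided convolution or pooling
would discard — the property that matters for very small objects.

Channel stacking order: sub-maps ``f[i, j] = x[i::scale, j::scale, :]`` are
concatenated with the row offset ``i`` varying fastest, i.e.
``[f00, f10, f01, f11]`` for scale 2.

In SPDConv the rearrangement is followed by a learned 1×1 convolution; the
optional ``mix`` argument marks where such a fixed linear channel mixing
would sit, without any learned parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["space_to_depth", "depth_to_space"]


def _offsets(scale: int) -> list[tuple[int, int]]:
    # (row, col) offsets with the row offset varying fastest
    return [(i, j) for j in range(scale) for i in range(scale)]


def space_to_depth(x: np.ndarray, scale: int, mix: np.ndarray | None = None) -> np.ndarray:
    """Rearrange spatial blocks into channels.

    Parameters
    ----------
    x : ndarray, shape (S_rows, S_cols, C)
        Input feature map; both spatial dims must be divisible by ``scale``.
    scale : int
        Block size, >= 2.
    mix : ndarray, optional
        A ``(C_out, C·scale²)`` matrix applied per output pixel — the slot of
        SPDConv's trailing 1×1 convolution, as a fixed linear map.

    Returns
    -------
    ndarray, shape (S_rows/scale, S_cols/scale, C·scale²) (or C_out with mix).
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected a 3-D (rows, cols, channels) array, got ndim={x.ndim}")
    if scale < 2:
        raise ValueError(f"scale must be >= 2, got {scale}")
    rows, cols, _ = x.shape
    if rows % scale or cols % scale:
        raise ValueError(
            f"spatial dims ({rows}, {cols}) must be divisible by scale {scale}"
        )
    out = np.concatenate([x[i::scale, j::scale, :] for i, j in _offsets(scale)], axis=2)
    if mix is not None:
        mix = np.asarray(mix)
        if mix.shape[1] != out.shape[2]:
            raise ValueError(
                f"mix matrix expects {mix.shape[1]} channels, map has {out.shape[2]}"
            )
        out = out @ mix.T
    return out


def depth_to_space(x: np.ndarray, scale: int) -> np.ndarray:
    """Exact inverse of :func:`space_to_depth` (without channel mixing)."""
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"expected a 3-D (rows, cols, channels) array, got ndim={x.ndim}")
    if scale < 2:
        raise ValueError(f"scale must be >= 2, got {scale}")
    rows, cols, chans = x.shape
    if chans % (scale * scale):
        raise ValueError(
            f"channel count {chans} must be divisible by scale²={scale * scale}"
        )
    c1 = chans // (scale * scale)
    out = np.empty((rows * scale, cols * scale, c1), dtype=x.dtype)
    for k, (i, j) in enumerate(_offsets(scale)):
        out[i::scale, j::scale, :] = x[:, :, k * c1 : (k + 1) * c1]
    return out
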