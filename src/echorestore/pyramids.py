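"""Gaussian and Laplacian image pyramids with exact collapse.

Images are 2-D float64 arrays with luminance nominally in [0, 1].  A
Gaussian pyramid is the sequence of blur-then-decimate reductions of the
input; a Laplacian pyramid stores the band-pass differences
``L_l = G_l - u(G_{l+1})`` plus the coarsest Gaussian residual, and
collapses back to the input exactly (to floating-point round-off),
because reduction and expansion use the same fixed separable kernel.

The low-pass kernel is the 5-tap binomial ``[1, 4, 6, 4, 1] / 16``,
which preserves constant images; boundaries are handled by symmetric
(mirror) reflection.  Level ``l+1`` has ``ceil(dim / 2)`` pixels per
axis, so any input size is admissible; expansion crops the upsampled
grid to the target level's exact shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "Pyramid",
    "as_image",
    "build_gaussian_pyramid",
    "build_laplacian_pyramid",
    "collapse_laplacian",
]

# 5-tap binomial low-pass; sums to 1, so constants survive reduction.
_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def as_image(values: Iterable) -> np.ndarray:
    """Validate and coerce ``values`` to a 2-D float64 luminance grid.

    Raises ``ValueError`` for non-2-D input, empty axes, or non-finite
    entries.  The nominal range is [0, 1] but is not enforced here:
    intermediate band-pass images are signed.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2-D, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image axes must be >= 1, got shape={arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class Pyramid:
    """Ordered multi-resolution stack, finest (level 0) to coarsest.

    ``kind`` is ``"gaussian"`` or ``"laplacian"``.  For a Laplacian
    pyramid the last level is the coarsest Gaussian residual; all other
    levels are band-pass differences.
    """

    kind: str
    levels: tuple

    def __post_init__(self):
        if self.kind not in ("gaussian", "laplacian"):
            raise ValueError(f"unknown pyramid kind {self.kind!r}")
        if len(self.levels) < 1:
            raise ValueError("pyramid needs at least one level")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _blur(arr: np.ndarray) -> np.ndarray:
    """Separable binomial blur on the last two axes, mirror boundaries."""
    out = convolve1d(arr, _KERNEL, axis=-2, mode="reflect")
    return convolve1d(out, _KERNEL, axis=-1, mode="reflect")


def _reduce(arr: np.ndarray) -> np.ndarray:
    """Blur then keep every second sample (ceil-halving)."""
    return _blur(arr)[..., ::2, ::2]


def _expand(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Upsample the last two axes to ``shape`` (zero-insert + blur x2).

    The coarse grid is symmetric-padded by one pixel before
    zero-insertion so that boundary pixels see the full alternating
    sample/zero pattern; without the pad a constant image would not
    expand to a constant at its borders.
    """
    h, w = shape
    pad = [(0, 0)] * (arr.ndim - 2) + [(1, 1), (1, 1)]
    padded = np.pad(arr, pad, mode="symmetric")
    up_shape = padded.shape[:-2] + (2 * padded.shape[-2], 2 * padded.shape[-1])
    up = np.zeros(up_shape, dtype=np.float64)
    up[..., ::2, ::2] = padded
    up = convolve1d(up, 2.0 * _KERNEL, axis=-2, mode="reflect")
    up = convolve1d(up, 2.0 * _KERNEL, axis=-1, mode="reflect")
    # offset 2 skips the two fine-grid rows/cols introduced by the pad
    return up[..., 2 : 2 + h, 2 : 2 + w]


def _check_levels(shape: tuple[int, int], n_levels: int) -> None:
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if 2 ** (n_levels - 1) > min(shape):
        raise ValueError(
            f"{n_levels} levels need min dimension >= {2 ** (n_levels - 1)}, "
            f"got shape {shape}"
        )


def build_gaussian_pyramid(image, n_levels: int) -> Pyramid:
    """Successively blur-and-decimate ``image`` into ``n_levels`` grids."""
    img = as_image(image)
    _check_levels(img.shape, n_levels)
    levels = [img.copy()]
    for _ in range(n_levels - 1):
        levels.append(_reduce(levels[-1]))
    return Pyramid("gaussian", tuple(levels))


def build_laplacian_pyramid(image, n_levels: int) -> Pyramid:
    """Band-pass decomposition: ``L_l = G_l - u(G_{l+1})`` + residual."""
    gauss = build_gaussian_pyramid(image, n_levels)
    levels = [
        gauss.levels[l] - _expand(gauss.levels[l + 1], gauss.levels[l].shape)
        for l in range(n_levels - 1)
    ]
    levels.append(gauss.levels[-1].copy())
    return Pyramid("laplacian", tuple(levels))


def collapse_laplacian(pyr: Pyramid) -> np.ndarray:
    """Recursive coarse-to-fine reconstruction ``G_l = L_l + u(G_{l+1})``."""
    if pyr.kind != "laplacian":
        raise ValueError(f"cannot collapse a {pyr.kind!r} pyramid")
    out = pyr.levels[-1]
    for band in reversed(pyr.levels[:-1]):
        out = band + _expand(out, band.shape)
    return out
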