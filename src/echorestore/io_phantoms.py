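"""Grayscale image I/O and synthetic echo-phantom generation.

The phantoms stand in for echocardiographic acquisitions: a clean
piecewise scene (a two-tone step, a pair of elliptical "chambers" on a
dark field, or a checkerboard) is degraded by unit-mean multiplicative
gamma speckle — the standard desk-scale ultrasound surrogate — and
additive Gaussian noise, then clipped to [0, 1].  An optional
rectangular or disk hole yields a repair mask for the inpainting
pipeline.  Every generator is a pure function of its spec, seed
included, so fixtures are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .pyramids import as_image

__all__ = ["HoleSpec", "PhantomSpec", "make_phantom", "read_image", "write_image"]


@dataclass(frozen=True)
class HoleSpec:
    """Region to knock out: ``shape`` "rect" (height x width box) or
    "disk" (radius ``size[0]``), centred at ``center`` (row, col)."""

    shape: str
    center: tuple
    size: tuple

    def __post_init__(self):
        if self.shape not in ("rect", "disk"):
            raise ValueError(f"unknown hole shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple = (128, 128)
    scene: str = "step"  # step | ellipse-chambers | checkerboard
    tones: tuple = (0.2, 0.8)
    cell: int = 8  # checkerboard cell side, px
    speckle_shape: float | None = None  # gamma shape; None = no speckle
    noise_sd: float = 0.0
    hole: HoleSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scene not in ("step", "ellipse-chambers", "checkerboard"):
            raise ValueError(f"unknown scene {self.scene!r}")
        if any(not 0.0 <= t <= 1.0 for t in self.tones):
            raise ValueError("tones must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle shape must be > 0")


def _scene(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.size
    t = spec.tones
    if spec.scene == "step":
        img = np.full((h, w), t[0])
        img[:, w // 2 :] = t[1] if len(t) > 1 else t[0]
        return img
    if spec.scene == "checkerboard":
        rr, cc = np.indices((h, w))
        board = ((rr // spec.cell) + (cc // spec.cell)) % 2
        return np.where(board == 0, t[0], t[1] if len(t) > 1 else t[0])
    # ellipse-chambers: dark field with two bright cavities, loosely
    # mimicking a long-axis view of left ventricle + atrium
    bg = t[0]
    fills = list(t[1:]) or [min(bg + 0.5, 1.0)]
    img = np.full((h, w), bg)
    rr, cc = np.indices((h, w))
    chambers = [
        ((0.38 * h, 0.35 * w), (0.24 * h, 0.22 * w)),
        ((0.68 * h, 0.62 * w), (0.16 * h, 0.20 * w)),
    ]
    for i, ((cr, ccen), (ar, ac)) in enumerate(chambers):
        inside = ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0
        img[inside] = fills[min(i, len(fills) - 1)]
    return img


def _hole_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.size
    mask = np.zeros((h, w), dtype=bool)
    if spec.hole is None:
        return mask
    hole = spec.hole
    r, c = hole.center
    if hole.shape == "rect":
        hh, ww = hole.size
        r0, c0 = r - hh // 2, c - ww // 2
        if r0 < 0 or c0 < 0 or r0 + hh > h or c0 + ww > w:
            raise ValueError("hole rectangle exceeds image bounds")
        mask[r0 : r0 + hh, c0 : c0 + ww] = True
    else:
        radius = hole.size[0]
        if r - radius < 0 or c - radius < 0 or r + radius >= h or c + radius >= w:
            raise ValueError("hole disk exceeds image bounds")
        rr, cc = np.indices((h, w))
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    return mask


def make_phantom(spec: PhantomSpec):
    """Return ``(image, truth, mask)`` for the phantom ``spec``.

    ``truth`` is the clean scene; ``image`` is truth times unit-mean
    gamma speckle (shape parameter ``speckle_shape``; larger = milder),
    plus N(0, noise_sd) additive noise, clipped to [0, 1]; ``mask``
    marks the hole (all False when no hole is requested).
    """
    truth = _scene(spec)
    mask = _hole_mask(spec)
    rng = np.random.default_rng(spec.seed)
    image = truth.copy()
    if spec.speckle_shape is not None:
        image = image * rng.gamma(
            spec.speckle_shape, 1.0 / spec.speckle_shape, size=truth.shape
        )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=truth.shape)
    return np.clip(image, 0.0, 1.0), truth, mask


def read_image(path) -> np.ndarray:
    """Load an 8- or 16-bit grayscale PNG/TIFF as a [0, 1] float grid."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"color images are not supported (got {arr.shape[2]} channels)"
        )
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise ValueError(
        f"unsupported bit depth {arr.dtype}; expected uint8 or uint16"
    )


def write_image(grid, path, bitdepth: int = 8) -> None:
    """Write a [0, 1] float grid as 8- or 16-bit grayscale PNG/TIFF."""
    img = np.clip(as_image(grid), 0.0, 1.0)
    if bitdepth == 8:
        out = np.rint(img * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        out = np.rint(img * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bitdepth must be 8 or 16, got {bitdepth}")
    iio.imwrite(path, out)
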