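"""Exemplar-based sample-block-matching restoration of masked regions.

Masked pixels are filled patch by patch.  Each iteration picks the
fill-front pixel with the highest priority, finds the fully-known
source patch that best matches the target patch on its known pixels
(masked sum of squared differences, computed by point-wise
multiplication with the known-pixel indicator), and copies the source
values into the unknown positions.

Priority is the classic confidence x data-term product, with one
deliberate twist: the data term (isophote strength across the front) is
evaluated on the *structure* component of the image — the
edge-preserving smoothed version from :mod:`echorestore.structure_filter`
— so that the fill is guided along the main structural areas rather
than being distracted by speckle texture.  Matching itself uses the
original intensities, which preserves texture in the fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import binary_dilation

from .pyramids import as_image
from .structure_filter import FilterConfig, decompose

__all__ = ["PatchSpec", "InpaintState", "priority", "best_match", "inpaint_image"]

#: floor of the data term; keeps structure-free front pixels fillable
_DATA_EPS = 1e-3

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PatchSpec:
    """A (2k+1)-sided square block centred at ``center`` (0-based row, col)."""

    center: tuple
    k: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("patch half-width k must be >= 1")

    @property
    def side(self) -> int:
        return 2 * self.k + 1


@dataclass
class InpaintState:
    """Bookkeeping of an exemplar fill in progress.

    mask:       current unknown region (True = still to repair).
    source:     originally-known region; candidate patches come only
                from here, so synthesized pixels are never re-copied.
    confidence: 1 on originally-known pixels, 0 on never-filled ones,
                the filling pixel's C(p) once filled.
    filled:     working image (known pixels of the input + fills so far).
    k:          patch half-width used throughout the fill.
    """

    mask: np.ndarray
    source: np.ndarray
    confidence: np.ndarray
    filled: np.ndarray
    k: int
    _cand_patches: np.ndarray = field(default=None, repr=False)
    _cand_centers: np.ndarray = field(default=None, repr=False)

    @property
    def front(self) -> np.ndarray:
        """Boolean grid of unknown pixels 4-adjacent to a known pixel."""
        known = ~self.mask
        return self.mask & binary_dilation(known, structure=_CROSS)

    def front_pixels(self) -> np.ndarray:
        """Front coordinates in scan (row-major) order, shape (n, 2)."""
        return np.argwhere(self.front)


def make_state(image: np.ndarray, mask: np.ndarray, k: int) -> InpaintState:
    """Initial fill state for ``image`` with unknown region ``mask``."""
    img = as_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("mask is empty: nothing to repair")
    if mask.all():
        raise ValueError("mask covers the entire image: nothing to copy from")
    state = InpaintState(
        mask=mask.copy(),
        source=~mask,
        confidence=(~mask).astype(np.float64),
        filled=img.copy(),
        k=k,
    )
    _index_candidates(state)
    return state


def _index_candidates(state: InpaintState) -> None:
    """Enumerate all fully-known candidate patches once, in scan order."""
    side = 2 * state.k + 1
    h, w = state.filled.shape
    if h < side or w < side:
        raise ValueError(f"image smaller than the {side}x{side} patch")
    known_windows = sliding_window_view(state.source, (side, side))
    ok = known_windows.all(axis=(2, 3))
    centers = np.argwhere(ok) + state.k  # window corner -> centre
    if centers.size == 0:
        raise ValueError("no fully-known source patch exists for this k")
    patch_windows = sliding_window_view(state.filled, (side, side))
    state._cand_patches = patch_windows[ok].copy()
    state._cand_centers = centers


def _patch_bounds(shape: tuple, center: tuple, k: int):
    """In-image bounds of the patch and matching offsets within the block."""
    r, c = center
    h, w = shape
    r0, r1 = max(r - k, 0), min(r + k + 1, h)
    c0, c1 = max(c - k, 0), min(c + k + 1, w)
    return (r0, r1, c0, c1), (r0 - (r - k), c0 - (c - k))


def _confidence_term(state: InpaintState, p: tuple) -> float:
    (r0, r1, c0, c1), _ = _patch_bounds(state.mask.shape, p, state.k)
    conf = state.confidence[r0:r1, c0:c1]
    known = ~state.mask[r0:r1, c0:c1]
    return float(np.sum(conf * known) / conf.size)


def _data_term(state: InpaintState, grad_s: tuple, p: tuple) -> float:
    r, c = p
    known = (~state.mask).astype(np.float64)
    h, w = known.shape
    # central differences on the known-indicator give the front normal
    nr = (known[min(r + 1, h - 1), c] - known[max(r - 1, 0), c]) / 2.0
    nc = (known[r, min(c + 1, w - 1)] - known[r, max(c - 1, 0)]) / 2.0
    norm = np.hypot(nr, nc)
    if norm == 0.0:
        return _DATA_EPS
    sr, sc = grad_s[0][r, c], grad_s[1][r, c]
    iso_r, iso_c = -sc, sr  # isophote: gradient rotated 90 degrees
    return abs(iso_r * nr / norm + iso_c * nc / norm) + _DATA_EPS


def priority(state: InpaintState, structure: np.ndarray, p: tuple) -> float:
    """P(p) = C(p) * D(p) for a pixel ``p`` on the fill front.

    C(p) is the summed confidence of known pixels in the patch over the
    patch area; D(p) is the strength of the structure-image isophote
    across the front normal, floored at a small epsilon so flat regions
    remain fillable.
    """
    if not state.front[p[0], p[1]]:
        raise ValueError(f"pixel {p} is not on the fill front")
    grad_s = np.gradient(np.asarray(structure, dtype=np.float64))
    return _confidence_term(state, p) * _data_term(state, (grad_s[0], grad_s[1]), p)


def best_match(state: InpaintState, target: PatchSpec) -> PatchSpec:
    """Fully-known candidate patch minimising the masked SSD to ``target``.

    The SSD runs only over the target's currently-known in-image
    pixels, via point-wise multiplication with the known indicator.  A
    fully-unknown target has SSD 0 against every candidate.  Ties break
    in scan order (smallest row, then column).
    """
    if target.k != state.k:
        raise ValueError("target patch half-width must match the state's k")
    if state._cand_patches is None:
        _index_candidates(state)
    side = target.side
    block = np.zeros((side, side))
    weight = np.zeros((side, side))
    (r0, r1, c0, c1), (orow, ocol) = _patch_bounds(
        state.mask.shape, target.center, target.k
    )
    hh, ww = r1 - r0, c1 - c0
    block[orow : orow + hh, ocol : ocol + ww] = state.filled[r0:r1, c0:c1]
    weight[orow : orow + hh, ocol : ocol + ww] = ~state.mask[r0:r1, c0:c1]
    diff = state._cand_patches - block[None]
    ssd = np.einsum("nij,nij,ij->n", diff, diff, weight)
    idx = int(np.argmin(ssd))  # argmin returns the first min: scan order
    return PatchSpec(center=tuple(state._cand_centers[idx]), k=state.k)


def inpaint_image(image, mask, k: int = 4, cfg: FilterConfig | None = None) -> np.ndarray:
    """Fill the masked region of ``image`` by structure-guided block matching.

    Extracts the structure component once, then repeats: pick the
    max-priority front pixel, copy the best-matching source block into
    the unknown positions of its patch, set their confidence to C(p),
    update the front.  Originally-known pixels are never written, and
    every iteration fills at least the chosen front pixel, so the loop
    terminates within |mask| iterations.
    """
    img = as_image(image)
    state = make_state(img, mask, k)
    if cfg is None:
        cfg = FilterConfig()

    # structure map from the hole-neutralised image (hole = known mean)
    neutral = img.copy()
    neutral[state.mask] = float(img[state.source].mean())
    structure = decompose(neutral, cfg).structure
    grad_s = np.gradient(structure)

    max_iters = int(state.mask.sum())
    for _ in range(max_iters):
        if not state.mask.any():
            break
        front = state.front_pixels()
        conf = np.array([_confidence_term(state, tuple(p)) for p in front])
        data = np.array([_data_term(state, grad_s, tuple(p)) for p in front])
        p = tuple(front[int(np.argmax(conf * data))])
        cp = _confidence_term(state, p)

        target = PatchSpec(center=p, k=k)
        src = best_match(state, target)
        (r0, r1, c0, c1), (orow, ocol) = _patch_bounds(state.mask.shape, p, k)
        sr, sc = src.center
        src_block = state.filled[sr - k : sr + k + 1, sc - k : sc + k + 1]
        unknown = state.mask[r0:r1, c0:c1]
        region = state.filled[r0:r1, c0:c1]
        region[unknown] = src_block[orow : orow + (r1 - r0), ocol : ocol + (c1 - c0)][unknown]
        state.confidence[r0:r1, c0:c1][unknown] = cp
        state.mask[r0:r1, c0:c1] = False
    assert not state.mask.any()
    return state.filled
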