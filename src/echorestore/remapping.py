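"""Point-wise nonlinear remapping and its adaptive parameter fields.

The remapping

    r(i) = i - m_f * (i - g) * exp(-(i - g)^2 / (2 sigma_r^2))

pulls pixel values toward a reference coefficient ``g`` (a Gaussian
pyramid coefficient at the matching scale and position) when they lie
within roughly ``sigma_r`` of it, and leaves values far from ``g``
untouched.  ``sigma_r`` therefore acts as a contour-discrimination
threshold: fluctuations smaller than it are treated as detail/texture
and attenuated, excursions larger than it are treated as edges and
preserved.  ``m_f`` in [0, 1] scales the attenuation (0 = identity).

For spatially adaptive filtering, ``sigma_r`` and ``m_f`` become
per-pixel matrices derived from the local intensity variance: busy
(high-variance) neighbourhoods get a smaller threshold so genuine
structure is not smoothed away, flat neighbourhoods a larger one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .pyramids import as_image

__all__ = [
    "RemapParams",
    "LocalVarianceField",
    "AdaptiveParamField",
    "remap",
    "local_variance",
    "adaptive_fields",
]

#: regulariser added to the image-mean variance so flat images divide cleanly
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class RemapParams:
    """Parameters of the point-wise mapping.

    ``g``, ``sigma_r`` and ``m_f`` may be scalars or broadcastable
    arrays (per-pixel adaptive use).  ``sigma_r`` must be strictly
    positive; ``m_f`` in [0, 1] smooths, 0 is the identity.
    """

    g: object
    sigma_r: object
    m_f: object

    def __post_init__(self):
        if np.any(np.asarray(self.sigma_r, dtype=float) <= 0):
            raise ValueError("sigma_r must be strictly positive")
        if not np.all(np.isfinite(np.asarray(self.m_f, dtype=float))):
            raise ValueError("m_f must be finite")


def remap(i, params: RemapParams):
    """Apply the Gaussian detail-attenuation mapping to intensity ``i``.

    Total and continuous in ``i``; fixed point at ``i == g``; approaches
    the identity as ``|i - g|`` grows, with the largest deviation
    ``m_f * sigma_r * exp(-1/2)`` attained at ``|i - g| == sigma_r``.
    """
    i = np.asarray(i, dtype=np.float64)
    g = np.asarray(params.g, dtype=np.float64)
    sigma_r = np.asarray(params.sigma_r, dtype=np.float64)
    m_f = np.asarray(params.m_f, dtype=np.float64)
    d = i - g
    return i - m_f * d * np.exp(-(d * d) / (2.0 * sigma_r * sigma_r))


@dataclass(frozen=True)
class LocalVarianceField:
    """Per-pixel population variance over a (2k+1)^2 mirror-padded window."""

    values: np.ndarray
    k: int


def local_variance(image, k: int) -> LocalVarianceField:
    """Population variance of each (2k+1)^2 neighbourhood.

    Windows are mirror-padded at the image boundary.  Computed as
    ``E[x^2] - E[x]^2`` with uniform box means; the tiny negative values
    that cancellation can produce are clipped to zero.
    """
    img = as_image(image)
    if k < 1:
        raise ValueError(f"window half-width k must be >= 1, got {k}")
    size = 2 * k + 1
    mean = uniform_filter(img, size=size, mode="reflect")
    mean_sq = uniform_filter(img * img, size=size, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return LocalVarianceField(values=var, k=k)


@dataclass(frozen=True)
class AdaptiveParamField:
    """Per-pixel threshold and amplitude matrices.

    ``sigma_ra`` is strictly positive and strictly decreasing in the
    local variance; ``m_fa`` shares its relative attenuation profile.
    """

    sigma_ra: np.ndarray
    m_fa: np.ndarray
    base_sigma: float
    base_mf: float


def adaptive_fields(
    V: LocalVarianceField, base_sigma: float, base_mf: float
) -> AdaptiveParamField:
    """Derive adaptive parameter matrices from the local variance.

    Uses the saturating inverse relation

        sigma_ra(p) = sigma_0 * Vbar / (Vbar + V(p)),
        m_fa(p)     = m_0 * sigma_ra(p) / sigma_0,

    where ``Vbar`` is the image-mean local variance (plus a 1e-12
    regulariser).  Both fields are antitone in ``V(p)``: zero variance
    gives the full base value (strongest smoothing), variance equal to
    the image mean gives exactly half of it, and the fields scale
    linearly in their base parameters.
    """
    if base_sigma <= 0:
        raise ValueError(f"base_sigma must be > 0, got {base_sigma}")
    v = np.asarray(V.values, dtype=np.float64)
    vbar = float(np.mean(v)) + _VAR_EPS
    sigma_ra = base_sigma * vbar / (vbar + v)
    m_fa = base_mf * sigma_ra / base_sigma
    return AdaptiveParamField(
        sigma_ra=sigma_ra, m_fa=m_fa, base_sigma=base_sigma, base_mf=base_mf
    )
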