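"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (double loops,
exact-fraction enumeration) and never calls the implementation paths it
is used to check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def naive_blur(img: np.ndarray) -> np.ndarray:
    """Separable 5-tap blur with symmetric padding, explicit loops."""
    h, w = img.shape
    padded = np.pad(img, 2, mode="symmetric")
    tmp = np.zeros((h, w + 4))
    for r in range(h):
        for c in range(w + 4):
            tmp[r, c] = sum(KERNEL[t] * padded[r + t, c] for t in range(5))
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = sum(KERNEL[t] * tmp[r, c + t] for t in range(5))
    return out


def naive_reduce(img: np.ndarray) -> np.ndarray:
    return naive_blur(img)[::2, ::2]


def naive_expand(img: np.ndarray, shape: tuple) -> np.ndarray:
    h, w = shape
    padded = np.pad(img, 1, mode="symmetric")
    up = np.zeros((2 * padded.shape[0], 2 * padded.shape[1]))
    up[::2, ::2] = padded
    k2 = 2.0 * KERNEL
    ph, pw = up.shape
    up_p = np.pad(up, 2, mode="symmetric")
    tmp = np.zeros((ph, pw + 4))
    for r in range(ph):
        for c in range(pw + 4):
            tmp[r, c] = sum(k2[t] * up_p[r + t, c] for t in range(5))
    out = np.zeros((ph, pw))
    for r in range(ph):
        for c in range(pw):
            out[r, c] = sum(k2[t] * tmp[r, c + t] for t in range(5))
    return out[2 : 2 + h, 2 : 2 + w]


def naive_gaussian_levels(img: np.ndarray, n: int) -> list:
    levels = [img.copy()]
    for _ in range(n - 1):
        levels.append(naive_reduce(levels[-1]))
    return levels


def naive_multiscale_filter(img: np.ndarray, n_levels: int, sigma: float, mf: float) -> np.ndarray:
    """Exhaustive per-coefficient filter using only the naive primitives."""
    gauss = naive_gaussian_levels(img, n_levels)
    out_levels = []
    for level in range(n_levels - 1):
        gl = gauss[level]
        band = np.zeros_like(gl)
        for x in range(gl.shape[0]):
            for y in range(gl.shape[1]):
                g = gl[x, y]
                d = img - g
                remapped = img - mf * d * np.exp(-(d * d) / (2 * sigma * sigma))
                rl = naive_gaussian_levels(remapped, level + 2)
                lap = rl[level] - naive_expand(rl[level + 1], rl[level].shape)
                band[x, y] = lap[x, y]
        out_levels.append(band)
    out = gauss[-1].copy()
    for band in reversed(out_levels):
        out = band + naive_expand(out, band.shape)
    return np.clip(out, 0.0, 1.0)


def naive_local_variance(img: np.ndarray, k: int) -> np.ndarray:
    h, w = img.shape
    padded = np.pad(img, k, mode="symmetric")
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + 2 * k + 1, c : c + 2 * k + 1]
            out[r, c] = win.var()
    return out


def brute_force_best_match(filled, known_now, known_orig, center, k):
    """Masked-SSD argmin over all fully-originally-known patches."""
    h, w = filled.shape
    r, c = center
    best = None
    best_ssd = None
    for sr in range(k, h - k):
        for sc in range(k, w - k):
            if not known_orig[sr - k : sr + k + 1, sc - k : sc + k + 1].all():
                continue
            ssd = 0.0
            for dr in range(-k, k + 1):
                for dc in range(-k, k + 1):
                    tr, tc = r + dr, c + dc
                    if 0 <= tr < h and 0 <= tc < w and known_now[tr, tc]:
                        diff = filled[tr, tc] - filled[sr + dr, sc + dc]
                        ssd += diff * diff
            if best_ssd is None or ssd < best_ssd - 1e-12:
                best_ssd, best = ssd, (sr, sc)
    return best


def enumerate_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating rank assignments."""
    n1, n = len(x), len(x) + len(y)
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == n, "oracle assumes no ties"
    ranks_x = [pooled.index(v) + 1 for v in x]
    w_obs = sum(ranks_x)
    mu = n1 * (n + 1) / 2
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def enumerate_fisher_p(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(aa: int) -> Fraction:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return Fraction(0)
        return Fraction(
            math.comb(r1, aa) * math.comb(r2, cc), math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + Fraction(1, 10**9)):
            total += p
    return float(total)


def concordance_auc(scores, labels) -> float:
    """AUC as the pairwise concordance fraction, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total
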