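"""Naive per-pixel reference implementations of the 15 image features.

Deliberately independent of the package implementation: HSV via the
standard-library ``colorsys``, Lab via the published sRGB -> XYZ -> Lab
formulas (D65, 2 degrees), texture statistics by direct per-pixel counting
and summation.  Used only as test oracles.
"""

import colorsys
import math

import numpy as np

# Published sRGB -> XYZ (D65) matrix and reference white.
_XYZ_FROM_RGB = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
# reference white = image of (1, 1, 1) under the matrix
_WHITE = tuple(float(v) for v in _XYZ_FROM_RGB.sum(axis=1))


def _srgb_linearize(c: float) -> float:
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def _lab_f(t: float) -> float:
    eps = (6.0 / 29.0) ** 3
    return t ** (1.0 / 3.0) if t > eps else t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0


def _pixel_lab(r: float, g: float, b: float) -> tuple[float, float, float]:
    lin = np.array([_srgb_linearize(r), _srgb_linearize(g), _srgb_linearize(b)])
    x, y, z = _XYZ_FROM_RGB @ lin
    fx = _lab_f(x / _WHITE[0])
    fy = _lab_f(y / _WHITE[1])
    fz = _lab_f(z / _WHITE[2])
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def naive_features(pixels: np.ndarray, bit_depth: int = 8,
                   n_levels: int = 256) -> dict[str, float]:
    """All 15 features by explicit per-pixel loops."""
    max_val = 2**bit_depth - 1
    h, w, _ = pixels.shape
    n = h * w
    sums = {k: 0.0 for k in
            ("R", "G", "B", "H", "S", "V", "L_star", "a_star", "b_star")}
    counts = [0] * n_levels
    for i in range(h):
        for j in range(w):
            r, g, b = (float(v) for v in pixels[i, j])
            sums["R"] += r
            sums["G"] += g
            sums["B"] += b
            hh, ss, vv = colorsys.rgb_to_hsv(r / max_val, g / max_val, b / max_val)
            sums["H"] += hh
            sums["S"] += ss
            sums["V"] += vv
            L, A, B2 = _pixel_lab(r / max_val, g / max_val, b / max_val)
            sums["L_star"] += L
            sums["a_star"] += A
            sums["b_star"] += B2
            gray = 0.299 * r + 0.587 * g + 0.114 * b
            counts[round(gray * (n_levels - 1) / max_val)] += 1
    out = {k: v / n for k, v in sums.items()}
    p = [c / n for c in counts]
    levels = [i * max_val / (n_levels - 1) for i in range(n_levels)]
    m = sum(z * pi for z, pi in zip(levels, p))
    var = sum((z - m) ** 2 * pi for z, pi in zip(levels, p))
    delta = math.sqrt(max(var, 0.0))
    mu3 = sum(((z - m) / max_val) ** 3 * pi for z, pi in zip(levels, p))
    U = sum(pi**2 for pi in p)
    e = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    dhat = delta / max_val
    r_smooth = 1.0 - 1.0 / (1.0 + dhat**2)
    out.update({"m": m, "delta": delta, "r": r_smooth, "mu3": mu3, "U": U, "e": e})
    return out
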