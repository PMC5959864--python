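"""Colour and texture descriptors for leaf-surface images.

A leaf photograph is summarised by 15 first-order statistics: the per-channel
means of three colour models (RGB native scale, HSV in [0, 1], CIE L*a*b*
under D65 / 2 degrees) and six statistics of the gray-level histogram --
mean ``m``, standard deviation ``delta``, smoothness ``r``, normalized third
moment ``mu3``, uniformity ``U`` and entropy ``e``.  All 15 are invariant to
pixel permutation; only R, G, B, m and delta carry the native intensity
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor

#: Canonical order of the 15 feature columns used everywhere in this package.
FEATURE_NAMES: tuple[str, ...] = (
    "R", "G", "B", "H", "S", "V",
    "L_star", "a_star", "b_star",
    "m", "delta", "r", "mu3", "U", "e",
)

#: Luminance weights used to collapse RGB to a single gray channel.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Default region-of-interest size (height, width) carved out of a full frame.
DEFAULT_ROI_SIZE = (1000, 2000)

# Published sRGB -> XYZ matrix (D65).  The reference white is its image of
# (1, 1, 1): with the rounded published coefficients this keeps the white
# anchor exact (pure white -> L* = 100, a* = b* = 0).
_XYZ_FROM_RGB = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_LAB_WHITE = _XYZ_FROM_RGB.sum(axis=1)


def _rgb2lab(unit_rgb: np.ndarray) -> np.ndarray:
    """Vectorized sRGB (in [0,1]) -> CIE L*a*b*, D65 / 2 degrees."""
    c = unit_rgb
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _XYZ_FROM_RGB.T / _LAB_WHITE
    eps = (6.0 / 29.0) ** 3
    f = np.where(xyz > eps, np.cbrt(xyz), xyz / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


@dataclass
class LeafImage:
    """An sRGB raster with optional sample metadata.

    ``pixels`` is an (H, W, 3) integer array with values in
    ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    sample_id: str | None = None
    moisture: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"pixels must be (H, W, 3), got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError(
                f"pixel values outside [0, {self.max_value}] for "
                f"{self.bit_depth}-bit image"
            )
        self.pixels = px

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class GrayHistogram:
    """First-order gray-level distribution.

    ``probabilities[i]`` is the fraction of pixels whose gray value maps to
    ``levels[i]``; ``scale`` is the native full-scale gray value (255 or
    65535) used to normalize the smoothness and third-moment statistics.
    """

    probabilities: np.ndarray
    levels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.min() < 0:
            raise ValueError("histogram probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("histogram probabilities must sum to 1")
        self.probabilities = p
        self.levels = np.asarray(self.levels, dtype=float)


@dataclass
class FeatureVector:
    """The 15 named image features of one sample."""

    R: float
    G: float
    B: float
    H: float
    S: float
    V: float
    L_star: float
    a_star: float
    b_star: float
    m: float
    delta: float
    r: float
    mu3: float
    U: float
    e: float
    sample_id: str | None = None
    moisture: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            bad = [n for n, v in zip(FEATURE_NAMES, vals) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad}")


def extract_roi(
    image: LeafImage,
    roi: tuple[int, int, int, int] | str = "auto",
    auto_size: tuple[int, int] = DEFAULT_ROI_SIZE,
) -> LeafImage:
    """Crop the analysis region from a full frame.

    ``roi="auto"`` takes the centered rectangle of ``auto_size``
    (height, width); if the image is smaller than that in either dimension
    the whole frame is used and a warning is emitted.  An explicit ROI is a
    ``(top, left, height, width)`` tuple and must lie inside the image.
    """
    h, w = image.shape
    if roi == "auto":
        rh, rw = auto_size
        if rh > h or rw > w:
            warnings.warn(
                f"image ({h}x{w}) smaller than requested ROI ({rh}x{rw}); "
                "using the whole frame",
                stacklevel=2,
            )
            return image
        top = (h - rh) // 2
        left = (w - rw) // 2
    else:
        top, left, rh, rw = roi
        if top < 0 or left < 0 or top + rh > h or left + rw > w:
            raise ValueError(
                f"ROI (top={top}, left={left}, h={rh}, w={rw}) does not fit "
                f"inside a {h}x{w} image"
            )
    return LeafImage(
        pixels=image.pixels[top : top + rh, left : left + rw],
        bit_depth=image.bit_depth,
        sample_id=image.sample_id,
        moisture=image.moisture,
    )


def color_features(image: LeafImage) -> dict[str, float]:
    """Mean colour coordinates in RGB, HSV and CIE L*a*b*.

    R, G, B are reported on the native integer scale; H, S, V on [0, 1];
    L* on [0, 100] with a*, b* unbounded opponent axes.  Hue of achromatic
    pixels is 0.
    """
    px = image.pixels.astype(float)
    unit = px / image.max_value
    hsv = _skcolor.rgb2hsv(unit)
    lab = _rgb2lab(unit)
    means_rgb = px.reshape(-1, 3).mean(axis=0)
    means_hsv = hsv.reshape(-1, 3).mean(axis=0)
    means_lab = lab.reshape(-1, 3).mean(axis=0)
    return {
        "R": means_rgb[0], "G": means_rgb[1], "B": means_rgb[2],
        "H": means_hsv[0], "S": means_hsv[1], "V": means_hsv[2],
        "L_star": means_lab[0], "a_star": means_lab[1], "b_star": means_lab[2],
    }


def gray_level_image(image: LeafImage) -> np.ndarray:
    """Weighted-luminance gray image on the native intensity scale."""
    px = image.pixels.astype(float)
    wr, wg, wb = GRAY_WEIGHTS
    return wr * px[..., 0] + wg * px[..., 1] + wb * px[..., 2]


def gray_histogram(image: LeafImage, n_levels: int = 256) -> GrayHistogram:
    """Quantize the luminance image into ``n_levels`` bins.

    Gray values are rescaled from the native range to ``[0, n_levels - 1]``
    and rounded to the nearest bin, so an 8-bit image with 256 levels bins
    at (rounded) native gray values, and a 16-bit image is binned at the
    equivalent 8-bit resolution.  Bin centers ``levels`` are reported back
    on the native scale.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    gray = gray_level_image(image)
    scale = float(image.max_value)
    idx = np.rint(gray * (n_levels - 1) / scale).astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=n_levels)
    p = counts / counts.sum()
    levels = np.arange(n_levels) * scale / (n_levels - 1)
    return GrayHistogram(probabilities=p, levels=levels, scale=scale)


def texture_features(hist: GrayHistogram) -> dict[str, float]:
    """Six first-order histogram statistics.

    m and delta are on the native gray scale.  The smoothness
    ``r = 1 - 1/(1 + (delta/scale)^2)`` and the third moment ``mu3`` use
    gray rescaled to [0, 1] so both stay bounded; uniformity ``U`` is the
    sum of squared probabilities and entropy ``e`` is in bits with the
    0*log(0) term defined as 0.
    """
    p = hist.probabilities
    z = hist.levels
    m = float(np.sum(z * p))
    var = float(np.sum((z - m) ** 2 * p))
    delta = float(np.sqrt(max(var, 0.0)))
    zn = z / hist.scale
    mn = m / hist.scale
    mu3 = float(np.sum((zn - mn) ** 3 * p))
    U = float(np.sum(p**2))
    pos = p[p > 0]
    e = float(-np.sum(pos * np.log2(pos)))
    dhat = delta / hist.scale
    r = 1.0 - 1.0 / (1.0 + dhat**2)
    return {"m": m, "delta": delta, "r": r, "mu3": mu3, "U": U, "e": e}


def extract_features(
    image: LeafImage,
    roi: tuple[int, int, int, int] | str | None = None,
    auto_size: tuple[int, int] = DEFAULT_ROI_SIZE,
    n_levels: int = 256,
) -> FeatureVector:
    """Full 15-feature vector of one image.

    ``roi=None`` analyses the whole frame; ``"auto"`` or an explicit
    rectangle first crops via :func:`extract_roi`.
    """
    if roi is not None:
        image = extract_roi(image, roi=roi, auto_size=auto_size)
    cf = color_features(image)
    tf = texture_features(gray_histogram(image, n_levels=n_levels))
    return FeatureVector(
        **cf, **tf, sample_id=image.sample_id, moisture=image.moisture
    )


def extract_feature_table(
    images: Iterable[LeafImage],
    roi: tuple[int, int, int, int] | str | None = None,
    auto_size: tuple[int, int] = DEFAULT_ROI_SIZE,
    n_levels: int = 256,
) -> pd.DataFrame:
    """Feature rows for a batch of images, in the canonical column order."""
    rows = []
    for img in images:
        fv = extract_features(img, roi=roi, auto_size=auto_size, n_levels=n_levels)
        row: dict[str, object] = {"sample_id": fv.sample_id}
        row.update(fv.as_dict())
        row["moisture"] = fv.moisture
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *FEATURE_NAMES, "moisture"])


def load_image(path: str | Path, sample_id: str | None = None,
               moisture: float | None = None) -> LeafImage:
    """Read a PNG (8-bit) or TIFF (8/16-bit) file into a :class:`LeafImage`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    if sample_id is None:
        sample_id = path.stem
    return LeafImage(pixels=arr, bit_depth=bit_depth,
                     sample_id=sample_id, moisture=moisture)


def save_image(image: LeafImage, path: str | Path) -> None:
    """Write 8-bit images as PNG, 16-bit as TIFF (chosen by the suffix)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.uint16 if image.bit_depth == 16 else np.uint8))
    else:
        from PIL import Image

        if image.bit_depth != 8:
            raise ValueError("PNG output supports 8-bit images; use TIFF for 16-bit")
        Image.fromarray(image.pixels.astype(np.uint8)).save(path)
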