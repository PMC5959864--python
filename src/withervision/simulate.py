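"""Seeded synthetic withering experiments.

The study design this module emulates: leaves wither for 11 h, sampled every
0.5 h (23 time points x 6 replicates = 138 samples) while the moisture mass
fraction falls from about 0.772 to 0.395.  Colour moves from bright green
toward dull brown and the surface texture flattens as the leaf dries, with
the texture-linked features dropping quickly until moisture reaches ~0.60
and slowly thereafter.

Two generators share that moisture trajectory:

* :func:`render_leaf_image` / :func:`render_withering_dataset` draw actual
  RGB rasters -- a base colour from moisture-dependent L*a*b* links plus a
  low-pass "wrinkle" field whose amplitude grows with moisture -- so the
  image-feature extractor can be exercised end to end.
* :func:`simulate_feature_table` skips rendering and draws the 15 features
  directly from per-feature monotone links plus noise; it is the fast
  substrate for model and pipeline tests.

Every function is deterministic given its seed; there is no global RNG
state anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import color as _skcolor

from .features import FEATURE_NAMES, LeafImage, save_image

__all__ = [
    "WitheringDesign",
    "PiecewiseLink",
    "RenderParams",
    "simulate_withering_series",
    "render_leaf_image",
    "render_withering_dataset",
    "simulate_feature_table",
    "default_feature_links",
]


@dataclass(frozen=True)
class WitheringDesign:
    """Layout of a withering time course.

    Defaults reproduce the reference design: 23 half-hourly time points with
    6 replicates each and moisture falling from 0.7718 to 0.3953 along a
    power-law curve with Gaussian replicate noise.
    """

    n_timepoints: int = 23
    replicates_per_timepoint: int = 6
    interval_h: float = 0.5
    w_start: float = 0.7718
    w_end: float = 0.3953
    decay_shape: float = 1.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2 or self.replicates_per_timepoint < 1:
            raise ValueError("need at least 2 time points and 1 replicate")
        if not (0.0 < self.w_end < self.w_start < 1.0):
            raise ValueError(
                "moisture bounds must satisfy 0 < w_end < w_start < 1 "
                f"(got w_start={self.w_start}, w_end={self.w_end})"
            )
        if self.decay_shape <= 0:
            raise ValueError("decay_shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.n_timepoints * self.replicates_per_timepoint

    def mean_curve(self) -> np.ndarray:
        """Noiseless moisture mean at each time point (non-increasing)."""
        t = np.arange(self.n_timepoints)
        frac = (t / (self.n_timepoints - 1)) ** self.decay_shape
        return self.w_start - (self.w_start - self.w_end) * frac


def simulate_withering_series(design: WitheringDesign) -> pd.DataFrame:
    """Sample manifest (sample_id, time_h, moisture) for one experiment.

    Replicate moisture is the time-point mean plus N(0, noise_sd) noise,
    clipped into (0, 1).
    """
    rng = np.random.default_rng(design.seed)
    means = design.mean_curve()
    rows = []
    for i, mu in enumerate(means):
        for j in range(design.replicates_per_timepoint):
            w = mu + rng.normal(0.0, design.noise_sd) if design.noise_sd else mu
            w = float(np.clip(w, 1e-4, 1 - 1e-4))
            rows.append(
                {
                    "sample_id": f"t{i:02d}_r{j}",
                    "time_h": i * design.interval_h,
                    "moisture": w,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PiecewiseLink:
    """Piecewise-linear monotone map from moisture to a feature value.

    ``value(w) = base + slope_lo * (min(w, breakpoint) - w_ref)
                      + slope_hi * max(w - breakpoint, 0)``

    ``base`` anchors the value at the dry reference moisture ``w_ref``.
    Equal slopes give a plain linear link; ``slope_hi > slope_lo >= 0``
    encodes the saturating "fast change while wet, slow change once
    moisture is below the breakpoint" trend.
    """

    base: float
    slope_lo: float
    slope_hi: float | None = None
    breakpoint: float = 0.60
    w_ref: float = 0.3953

    def __post_init__(self) -> None:
        if self.slope_hi is None:
            object.__setattr__(self, "slope_hi", self.slope_lo)

    def value(self, w: float | np.ndarray) -> float | np.ndarray:
        w = np.asarray(w, dtype=float)
        lo = np.minimum(w, self.breakpoint) - self.w_ref
        hi = np.maximum(w - self.breakpoint, 0.0)
        out = self.base + self.slope_lo * lo + self.slope_hi * hi
        return float(out) if out.ndim == 0 else out

    @property
    def sign(self) -> int:
        """Declared correlation sign with moisture (0 if flat)."""
        s = self.slope_lo + self.slope_hi
        return int(np.sign(s))

    def is_strictly_increasing(self) -> bool:
        return self.slope_lo > 0 and self.slope_hi > 0

    def is_strictly_decreasing(self) -> bool:
        return self.slope_lo < 0 and self.slope_hi < 0


# Base-colour links in L*a*b*: wetter (fresher) leaves are brighter
# (higher L*), greener (more negative a*) and slightly yellower (higher b*).
_DEFAULT_COLOR_LINKS: dict[str, PiecewiseLink] = {
    "L_star": PiecewiseLink(base=34.0, slope_lo=50.0),
    "a_star": PiecewiseLink(base=-5.0, slope_lo=-15.0, slope_hi=-35.0),
    "b_star": PiecewiseLink(base=18.0, slope_lo=8.0, slope_hi=40.0),
}

# Wrinkle amplitude in L* units: wet leaves have strong surface relief that
# collapses on drying, quickly above the 0.60 moisture breakpoint.
_DEFAULT_AMPLITUDE_LINK = PiecewiseLink(base=1.5, slope_lo=4.0, slope_hi=28.0)


@dataclass(frozen=True)
class RenderParams:
    """Controls for the leaf-image renderer.

    ``image_size`` is (height, width); the 400 x 200 default keeps the 2:1
    aspect of the 2000 x 1000 analysis region at desk-scale cost.
    """

    image_size: tuple[int, int] = (400, 200)
    color_links: Mapping[str, PiecewiseLink] = field(
        default_factory=lambda: dict(_DEFAULT_COLOR_LINKS)
    )
    texture_amplitude_link: PiecewiseLink = _DEFAULT_AMPLITUDE_LINK
    wrinkle_sigma: float = 6.0
    fine_noise_sd: float = 0.5
    bit_depth: int = 8

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        links = self.color_links
        if not links["L_star"].is_strictly_increasing():
            raise ValueError("L* link must be strictly increasing in moisture")
        if not links["a_star"].is_strictly_decreasing():
            raise ValueError("a* link must be strictly decreasing in moisture")
        amp = self.texture_amplitude_link
        if amp.slope_lo < 0 or amp.slope_hi < 0:
            raise ValueError("texture amplitude must be non-decreasing in moisture")

    def validate_breakpoints(self, design: WitheringDesign) -> None:
        for name, link in {**dict(self.color_links),
                           "amplitude": self.texture_amplitude_link}.items():
            if not (design.w_end < link.breakpoint < design.w_start):
                raise ValueError(
                    f"breakpoint of link '{name}' ({link.breakpoint}) outside "
                    f"the moisture range ({design.w_end}, {design.w_start})"
                )


def render_leaf_image(
    moisture: float,
    params: RenderParams | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> LeafImage:
    """Render one synthetic leaf-surface raster at the given moisture.

    The base colour comes from the L*a*b* links; a seeded, Gaussian
    low-pass wrinkle field (normalized to unit variance) scaled by the
    moisture-dependent texture amplitude is added to L*, with small
    per-pixel fine noise on all three channels, before conversion back to
    sRGB and quantization.
    """
    if not (0.0 < moisture < 1.0):
        raise ValueError(f"moisture must be in (0, 1), got {moisture}")
    if params is None:
        params = RenderParams()
    rng = np.random.default_rng(seed)
    h, w = params.image_size

    L0 = params.color_links["L_star"].value(moisture)
    a0 = params.color_links["a_star"].value(moisture)
    b0 = params.color_links["b_star"].value(moisture)
    amp = params.texture_amplitude_link.value(moisture)

    lab = np.empty((h, w, 3), dtype=float)
    lab[..., 0] = L0
    lab[..., 1] = a0
    lab[..., 2] = b0

    if amp > 0:
        raw = rng.standard_normal((h, w))
        field_ = gaussian_filter(raw, sigma=params.wrinkle_sigma, mode="reflect")
        sd = field_.std()
        if sd > 0:
            field_ = (field_ - field_.mean()) / sd
        lab[..., 0] += amp * field_
        # wrinkles shade chroma slightly as well as lightness
        lab[..., 1] += 0.2 * amp * field_
        lab[..., 2] += 0.3 * amp * field_
    if params.fine_noise_sd > 0:
        lab[..., 0] += rng.normal(0.0, params.fine_noise_sd, (h, w))
        lab[..., 1] += rng.normal(0.0, 0.3 * params.fine_noise_sd, (h, w))
        lab[..., 2] += rng.normal(0.0, 0.3 * params.fine_noise_sd, (h, w))

    rgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    max_val = 2 ** params.bit_depth - 1
    px = np.rint(rgb * max_val).astype(np.uint16 if params.bit_depth == 16 else np.uint8)
    return LeafImage(pixels=px, bit_depth=params.bit_depth,
                     sample_id=sample_id, moisture=moisture)


def render_withering_dataset(
    design: WitheringDesign,
    params: RenderParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[LeafImage] | None]:
    """Render the full withering series to images.

    Returns ``(manifest, images)``.  With ``out_dir`` set, images are
    written as PNG (8-bit) or TIFF (16-bit), the manifest gains an
    ``image_path`` column and the in-memory list is ``None``.  Per-sample
    render seeds are derived deterministically from ``design.seed``.
    """
    if params is None:
        params = RenderParams()
    params.validate_breakpoints(design)
    manifest = simulate_withering_series(design)
    child_seeds = np.random.SeedSequence(design.seed).generate_state(
        len(manifest) + 1
    )[1:] % (2**31)
    images: list[LeafImage] | None = [] if out_dir is None else None
    paths: list[str] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for k, row in manifest.iterrows():
        img = render_leaf_image(
            row["moisture"], params=params, seed=int(child_seeds[k]),
            sample_id=row["sample_id"],
        )
        if out_dir is None:
            images.append(img)  # type: ignore[union-attr]
        else:
            ext = "png" if params.bit_depth == 8 else "tiff"
            path = Path(out_dir) / f"{row['sample_id']}.{ext}"
            save_image(img, path)
            paths.append(str(path))
    if out_dir is not None:
        manifest = manifest.assign(image_path=paths)
    return manifest, images


def default_feature_links() -> dict[str, PiecewiseLink | None]:
    """Moisture links for all 15 features in the direct (image-free) generator.

    Signs and shapes mirror the observed feature-moisture structure:
    R, G, V, L* rise linearly with moisture; S, b*, m, delta, r, e rise with
    a fast-above-0.60 saturating shape; a* and U fall; B, H and mu3 carry no
    declared moisture dependence (``None``).
    """
    return {
        "R": PiecewiseLink(base=70.0, slope_lo=90.0),
        "G": PiecewiseLink(base=90.0, slope_lo=110.0),
        "B": None,
        "H": None,
        "S": PiecewiseLink(base=0.30, slope_lo=0.10, slope_hi=0.90),
        "V": PiecewiseLink(base=0.35, slope_lo=0.45),
        "L_star": PiecewiseLink(base=34.0, slope_lo=50.0),
        "a_star": PiecewiseLink(base=-5.0, slope_lo=-15.0, slope_hi=-35.0),
        "b_star": PiecewiseLink(base=18.0, slope_lo=8.0, slope_hi=40.0),
        "m": PiecewiseLink(base=80.0, slope_lo=40.0, slope_hi=160.0),
        "delta": PiecewiseLink(base=10.0, slope_lo=8.0, slope_hi=45.0),
        "r": PiecewiseLink(base=0.012, slope_lo=0.010, slope_hi=0.080),
        "mu3": None,
        "U": PiecewiseLink(base=0.055, slope_lo=-0.090),
        "e": PiecewiseLink(base=4.2, slope_lo=1.0, slope_hi=4.5),
    }


#: Baseline values used for features with no moisture link, and the default
#: per-feature noise standard deviations (diagonal noise covariance).
_FEATURE_BASELINES: dict[str, float] = {"B": 60.0, "H": 0.25, "mu3": 0.0005}
_FEATURE_NOISE_SD: dict[str, float] = {
    "R": 8.0, "G": 5.0, "B": 6.0, "H": 0.02, "S": 0.03, "V": 0.04,
    "L_star": 2.5, "a_star": 1.5, "b_star": 1.2,
    "m": 6.0, "delta": 2.0, "r": 0.004, "mu3": 0.0004, "U": 0.004, "e": 0.25,
}


def default_noise_cov() -> np.ndarray:
    """Default diagonal noise covariance over the 15 canonical features."""
    sds = np.array([_FEATURE_NOISE_SD[n] for n in FEATURE_NAMES])
    return np.diag(sds**2)


def simulate_feature_table(
    design: WitheringDesign,
    link_spec: Mapping[str, PiecewiseLink | None] | None = None,
    noise_cov: float | np.ndarray | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw the 15-feature table directly from moisture links plus noise.

    ``link_spec`` must name every canonical feature, mapping it to a
    :class:`PiecewiseLink` or ``None`` (no moisture dependence).
    ``noise_cov`` may be a full 15 x 15 covariance, a length-15 vector of
    variances, a scalar multiplier on the default diagonal covariance, or
    ``None`` for the defaults.  The returned frame is byte-reproducible
    for a fixed design and seed.
    """
    if link_spec is None:
        link_spec = default_feature_links()
    missing = [n for n in FEATURE_NAMES if n not in link_spec]
    if missing:
        raise ValueError(f"link_spec missing features: {missing}")

    cov = _coerce_noise_cov(noise_cov)
    manifest = simulate_withering_series(design)
    w = manifest["moisture"].to_numpy()
    n = len(w)

    X = np.empty((n, len(FEATURE_NAMES)))
    for j, name in enumerate(FEATURE_NAMES):
        link = link_spec[name]
        if link is None:
            X[:, j] = _FEATURE_BASELINES.get(name, 0.0)
        else:
            X[:, j] = link.value(w)

    rng = np.random.default_rng(design.seed if seed is None else seed)
    if np.any(cov):
        X = X + rng.multivariate_normal(
            np.zeros(len(FEATURE_NAMES)), cov, size=n, method="eigh"
        )
    out = manifest.copy()
    for j, name in enumerate(FEATURE_NAMES):
        out[name] = X[:, j]
    return out[["sample_id", "time_h", *FEATURE_NAMES, "moisture"]]


def _coerce_noise_cov(noise_cov: float | np.ndarray | None) -> np.ndarray:
    p = len(FEATURE_NAMES)
    if noise_cov is None:
        cov = default_noise_cov()
    else:
        arr = np.asarray(noise_cov, dtype=float)
        if arr.ndim == 0:
            cov = float(arr) * default_noise_cov()
        elif arr.ndim == 1:
            if arr.shape[0] != p:
                raise ValueError(f"variance vector must have length {p}")
            cov = np.diag(arr)
        elif arr.shape == (p, p):
            cov = arr
        else:
            raise ValueError(f"noise_cov must be scalar, length-{p} or {p}x{p}")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(eig.max(), 1.0):
        raise ValueError("noise covariance is not positive semi-definite")
    return cov
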