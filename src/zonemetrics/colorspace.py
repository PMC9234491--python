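"""Color-space conversions and intensity normalization.

H&E-stained sections are segmented downstream in two color spaces: a
subtractive CMYK representation (ink-like channels, used for the coarse
k-means clustering) and HSV (circular hue, used for peak-based
segmentation of stain colors).  Both conversions here are plain,
device-independent formulas — no ICC color management.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "RasterImage",
    "CMYKPlanes",
    "HSVPlanes",
    "rgb_to_cmyk",
    "rgb_to_hsv",
    "normalize_intensity",
]


@dataclass
class RasterImage:
    """An RGB raster with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        RGB values in [0, 1] (8-bit inputs divided by 255).
    pixel_size : float
        Physical edge length of one pixel (µm/px); 1.0 means
        uncalibrated, so areas come out in px².
    id : str
        Identifier carried into measurement provenance.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be H x W x 3, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.isfinite(self.pixels).all():
            idx = tuple(np.argwhere(~np.isfinite(self.pixels))[0])
            raise ValueError(f"non-finite pixel value at index {idx}")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class CMYKPlanes:
    """Cyan/magenta/yellow/key planes, each H×W in [0, 1]."""

    c: np.ndarray
    m: np.ndarray
    y: np.ndarray
    k: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.c.shape

    def stack(self) -> np.ndarray:
        """Pixels as an N×4 feature matrix (row-major flattening)."""
        return np.stack(
            [p.ravel() for p in (self.c, self.m, self.y, self.k)], axis=1
        )


@dataclass
class HSVPlanes:
    """Hue (circular, [0,1)), saturation and value planes.

    Pixels with zero saturation have undefined hue; it is stored as 0 and
    flagged in ``undefined_hue`` so hue-distance computations can skip
    them.
    """

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray
    undefined_hue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.undefined_hue is None:
            self.undefined_hue = self.s == 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


def rgb_to_cmyk(image: RasterImage) -> CMYKPlanes:
    """Naive ink-subtraction RGB→CMYK.

    K = 1 − max(R,G,B); C = (1−R−K)/(1−K) and analogously for M, Y, with
    C = M = Y = 0 wherever K = 1 (pure black).  Pure white maps to
    (0, 0, 0, 0).
    """
    rgb = image.pixels
    k = 1.0 - rgb.max(axis=2)
    denom = 1.0 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        cmy = (denom[..., None] - rgb) / denom[..., None]
    cmy[denom == 0.0, :] = 0.0
    cmy = np.clip(cmy, 0.0, 1.0)
    return CMYKPlanes(c=cmy[..., 0], m=cmy[..., 1], y=cmy[..., 2], k=k)


def cmyk_to_rgb(planes: CMYKPlanes) -> np.ndarray:
    """Inverse of :func:`rgb_to_cmyk`: R = (1−C)(1−K) etc."""
    cmy = np.stack([planes.c, planes.m, planes.y], axis=2)
    return (1.0 - cmy) * (1.0 - planes.k)[..., None]


def rgb_to_hsv(image: RasterImage) -> HSVPlanes:
    """Standard hexcone HSV; hue in [0, 1) with 1 wrapped to 0."""
    hsv = rgb2hsv(image.pixels)
    h = hsv[..., 0].copy()
    h[h >= 1.0] -= 1.0
    s = hsv[..., 1]
    undefined = s == 0.0
    h[undefined] = 0.0
    return HSVPlanes(h=h, s=s, v=hsv[..., 2], undefined_hue=undefined)


def normalize_intensity(
    image: RasterImage, low_pct: float = 0.01, high_pct: float = 0.99
) -> RasterImage:
    """Per-channel percentile contrast stretch.

    Controls for slide-to-slide stain intensity/contrast before
    clustering: within each channel, values at or below the ``low_pct``
    quantile map to 0, at or above ``high_pct`` map to 1, linearly in
    between.  Monotone within a channel.  A constant channel is returned
    unchanged with a warning.
    """
    if not (0.0 <= low_pct < high_pct <= 1.0):
        raise ValueError(
            f"require 0 <= low_pct < high_pct <= 1, got {low_pct}, {high_pct}"
        )
    out = np.empty_like(image.pixels)
    for ch in range(3):
        plane = image.pixels[..., ch]
        lo, hi = np.quantile(plane, [low_pct, high_pct])
        if hi <= lo:
            warnings.warn(
                f"channel {ch} is constant over the stretch percentiles; "
                "returned unchanged",
                stacklevel=2,
            )
            out[..., ch] = plane
        else:
            out[..., ch] = np.clip((plane - lo) / (hi - lo), 0.0, 1.0)
    return RasterImage(pixels=out, pixel_size=image.pixel_size, id=image.id)
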