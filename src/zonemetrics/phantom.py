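"""Synthetic H&E-like placental phantoms with analytic ground truth.

A phantom is an annular cross-section on a near-white background: a
pink labyrinth-zone (LZ) disc whose boundary is the polar curve
r(θ) = r_lz0 + A·sin(k_wave·θ), a purple junctional-zone (JZ) annulus
out to ``r_jz_outer``, and a dark decidua rim out to ``r_dec_outer``.
Circular background-colored holes emulate tissue-free space at a
controlled per-zone fraction, and i.i.d. Gaussian RGB noise emulates
stain/scan variation.  Because the border curve is analytic, its arc
length — and hence the target for border-length and tortuosity
recovery — is known to high precision.

This is a validation device, not a tissue model: real sections are
irregular, textured, and unevenly stained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.measure import approximate_polygon, find_contours
from skimage.morphology import disk

from .colorspace import RasterImage
from .config import SessionSpec
from .segmentation import DEFAULT_ZONE_REFS, ZONES

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "oracle_border_length",
    "make_session_from_truth",
]


@dataclass
class PhantomSpec:
    """Geometry, colors and noise of one synthetic section."""

    size: tuple[int, int] = (512, 512)  # (H, W)
    center: tuple[float, float] | None = None  # (cx, cy); default midpoint
    r_lz0: float = 100.0  # mean LZ radius, px
    wave_amplitude: float = 10.0  # A, px
    wave_number: int = 8  # k_wave (integer lobes)
    r_jz_outer: float = 160.0
    r_dec_outer: float = 220.0
    zone_colors: dict = field(
        default_factory=lambda: {z: tuple(DEFAULT_ZONE_REFS[z]) for z in ZONES})
    hole_fraction: dict = field(
        default_factory=lambda: {z: 0.05 for z in ZONES})
    hole_radius_range: tuple[float, float] = (3.0, 8.0)
    background_rgb: tuple[float, float, float] = (0.97, 0.97, 0.97)
    noise_sigma: float = 0.02
    seed: int = 0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        h, w = self.size
        if self.center is None:
            self.center = (w / 2.0, h / 2.0)
        if not (0 < self.r_lz0 - self.wave_amplitude):
            raise ValueError("wave amplitude must be smaller than r_lz0")
        if not (self.r_lz0 + self.wave_amplitude < self.r_jz_outer
                < self.r_dec_outer < min(h, w) / 2.0):
            raise ValueError(
                "require r_lz0 + A < r_jz_outer < r_dec_outer < min(H,W)/2")
        for z, f in self.hole_fraction.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"hole fraction for {z} must lie in [0, 1)")


@dataclass
class PhantomGroundTruth:
    """Analytically known answers for one generated phantom."""

    zone_masks: dict  # zone → bool raster (geometric, holes included)
    hole_raster: np.ndarray  # bool, all zones
    zone_pixel_areas: dict  # zone → pixel count
    hole_fractions: dict  # zone → realized fraction
    border_polyline: np.ndarray  # (N, 2) dense (x, y) samples of r(θ)
    border_arc_length: float  # px, from oracle_border_length
    image_id: str = ""
    seed: int = 0
    spec: PhantomSpec | None = None

    def tissue_pct(self, zone: str) -> float:
        return 100.0 * (1.0 - self.hole_fractions[zone])


def oracle_border_length(
    r0: float, amplitude: float, k_wave: int, n_samples: int = 100_000
) -> float:
    """Arc length of r(θ) = r0 + A·sin(k·θ) over one revolution.

    Trapezoidal integration of the polar speed sqrt(r² + (dr/dθ)²) on a
    dense uniform grid; exact (2πr0) when A = 0 and convergent to
    < 0.1 % change on doubling n_samples otherwise.
    """
    if n_samples < 10 * k_wave + 10:
        raise ValueError("n_samples too small for the wave number")
    theta = np.linspace(0.0, 2.0 * np.pi, n_samples + 1)
    r = r0 + amplitude * np.sin(k_wave * theta)
    dr = amplitude * k_wave * np.cos(k_wave * theta)
    speed = np.sqrt(r**2 + dr**2)
    return float(np.trapezoid(speed, theta))


def _place_holes(
    zone_mask: np.ndarray,
    target_frac: float,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
    xx: np.ndarray,
    yy: np.ndarray,
    existing: list,
    max_attempts: int = 20_000,
) -> tuple[np.ndarray, float]:
    """Seeded rejection sampling of non-overlapping discs inside a zone.

    Discs are entirely contained in the zone; the final disc is shrunk
    so the realized pixel fraction lands within 0.5 percentage points
    of the target.
    """
    holes = np.zeros_like(zone_mask)
    zone_px = int(zone_mask.sum())
    if target_frac <= 0.0 or zone_px == 0:
        return holes, 0.0
    target_px = target_frac * zone_px
    tol_px = 0.005 * zone_px
    edt = ndimage.distance_transform_edt(zone_mask)
    painted = 0
    attempts = 0
    r_lo, r_hi = radius_range
    while painted < target_px - tol_px / 2.0:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not reach hole fraction {target_frac} with radii "
                f"{radius_range} after {max_attempts} attempts")
        r_s = float(rng.uniform(r_lo, r_hi))
        needed = target_px - painted
        if np.pi * r_s**2 > needed + tol_px / 2.0:
            # shrink the final disc to land on the target — but never
            # below the configured minimum radius
            r_shrunk = float(np.sqrt(needed / np.pi))
            if r_shrunk >= r_lo:
                r_s = r_shrunk
            elif np.pi * r_lo**2 - needed <= tol_px:
                r_s = r_lo
            else:
                raise ValueError(
                    f"cannot reach hole fraction {target_frac}: the "
                    f"smallest allowed disc (radius {r_lo}) overshoots "
                    "the target beyond tolerance")
        cand = np.argwhere(edt > r_s + 1.0)
        if len(cand) == 0:
            continue
        i, j = cand[rng.integers(len(cand))]
        cx, cy = xx[i, j], yy[i, j]
        if any(np.hypot(cx - ex, cy - ey) <= r_s + er + 1.0
               for ex, ey, er in existing):
            continue
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_s**2
        new = disc & zone_mask & ~holes
        n_new = int(new.sum())
        if painted + n_new > target_px + tol_px:
            continue
        holes |= new
        painted += n_new
        existing.append((cx, cy, r_s))
    return holes, painted / zone_px


def generate_phantom(spec: PhantomSpec) -> tuple[RasterImage, PhantomGroundTruth]:
    """Render a phantom and its ground truth (truth is pre-noise).

    Deterministic: the same spec and seed give identical image bytes
    and ground truth.
    """
    h, w = spec.size
    cx, cy = spec.center
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    xx = jj + 0.5
    yy = ii + 0.5
    r = np.hypot(xx - cx, yy - cy)
    theta = np.arctan2(yy - cy, xx - cx)
    r_border = spec.r_lz0 + spec.wave_amplitude * np.sin(
        spec.wave_number * theta)

    zone_masks = {
        "LZ": r < r_border,
        "JZ": (r >= r_border) & (r < spec.r_jz_outer),
        "decidua": (r >= spec.r_jz_outer) & (r < spec.r_dec_outer),
    }

    rng = np.random.default_rng(spec.seed)
    hole_raster = np.zeros((h, w), dtype=bool)
    hole_fractions: dict[str, float] = {}
    existing: list = []
    for zone in ZONES:
        holes, realized = _place_holes(
            zone_masks[zone], spec.hole_fraction.get(zone, 0.0),
            spec.hole_radius_range, rng, xx, yy, existing)
        hole_raster |= holes
        hole_fractions[zone] = realized

    img = np.empty((h, w, 3))
    img[:] = np.asarray(spec.background_rgb)
    for zone in ZONES:
        rgb = hsv2rgb(np.asarray(spec.zone_colors[zone])[None, None, :])[0, 0]
        img[zone_masks[zone] & ~hole_raster] = rgb
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0)

    n_dense = max(4096, 64 * spec.wave_number)
    th = np.linspace(0.0, 2.0 * np.pi, n_dense + 1)
    rb = spec.r_lz0 + spec.wave_amplitude * np.sin(spec.wave_number * th)
    polyline = np.stack([cx + rb * np.cos(th), cy + rb * np.sin(th)], axis=1)

    image_id = f"phantom-seed{spec.seed}"
    truth = PhantomGroundTruth(
        zone_masks=zone_masks,
        hole_raster=hole_raster,
        zone_pixel_areas={z: int(zone_masks[z].sum()) for z in ZONES},
        hole_fractions=hole_fractions,
        border_polyline=polyline,
        border_arc_length=oracle_border_length(
            spec.r_lz0, spec.wave_amplitude, spec.wave_number),
        image_id=image_id,
        seed=spec.seed,
        spec=spec,
    )
    raster = RasterImage(pixels=img, pixel_size=spec.pixel_size, id=image_id)
    return raster, truth


def _mask_outline(mask: np.ndarray, dilate_px: int, tolerance: float = 0.5
                  ) -> np.ndarray:
    """Simplified (x, y) polygon of a mask's outer contour."""
    if not mask.any():
        raise ValueError("cannot outline an empty zone mask")
    work = mask
    if dilate_px > 0:
        work = ndimage.binary_dilation(mask, structure=disk(dilate_px))
    padded = np.pad(work.astype(float), 1)
    contours = find_contours(padded, 0.5)

    def ring_area(c):
        x, y = c[:, 1], c[:, 0]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    outer = max(contours, key=ring_area)
    outer = approximate_polygon(outer, tolerance=tolerance)
    # padded index coords → pixel-center coords: x = (col−1)+0.5
    return np.stack([outer[:, 1] - 0.5, outer[:, 0] - 0.5], axis=1)


def make_session_from_truth(
    truth: PhantomGroundTruth, dilate_px: int = 2
) -> SessionSpec:
    """Stand-in for a human tracing the zones: generous outlines.

    Each zone's outline is the outer contour of its ground-truth mask
    dilated by ``dilate_px``, simplified to ~0.5 px; annular zones get
    a filled outer contour (the pipeline's segmentation rules resolve
    the interior).  Cluster choice is left on "auto".
    """
    outlines = {
        zone: _mask_outline(truth.zone_masks[zone], dilate_px)
        for zone in ZONES
    }
    return SessionSpec(
        image_id=truth.image_id,
        cluster_index="auto",
        zone_outlines=outlines,
    )
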