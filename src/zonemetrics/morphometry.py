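"""Zone masks and section-level morphometry.

Turns zone outlines plus the color segmentation into per-zone pixel
masks, then computes the per-section quantities: total cross-section
area, per-zone areas, percentage of each zone containing tissue, the
length of the labyrinth–junctional (LZ–JZ) border, and the border's
tortuosity.  An exclusion step removes operator-marked regions
(e.g. chorionic plate or yolk-sac remnants) and recomputes everything.

Conventions: rasters are row-major with the origin at the top-left;
polygon vertices are (x, y) in pixel units, the center of pixel
(row i, col j) sitting at (j + 0.5, i + 0.5); a pixel belongs to a
polygon iff its center is inside under the even-odd rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Polygon

from .colorspace import RasterImage, rgb_to_cmyk, rgb_to_hsv, normalize_intensity
from .segmentation import (
    ZONES,
    ZoneAssignment,
    assign_zone_segment,
    background_mask,
    cluster_cmyk,
    hsv_color_distance,
    hsv_peak_segments,
    select_reference_cluster,
)

__all__ = [
    "ZoneOutline",
    "ZoneMask",
    "BorderPath",
    "SectionMeasurements",
    "SectionContext",
    "outline_to_mask",
    "zone_area",
    "tissue_fraction",
    "lz_jz_border",
    "border_tortuosity",
    "polygon_area",
    "apply_exclusion",
    "measure_section",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_BOX = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass
class ZoneOutline:
    """A closed polygon delimiting where one zone is to be analyzed."""

    zone: str
    polygon: np.ndarray  # (V, 2) vertices as (x, y), implicitly closed

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be a (V, 2) vertex array")


@dataclass
class ZoneMask:
    zone: str
    mask: np.ndarray  # bool raster
    tissue_mask: np.ndarray  # mask ∧ ¬background


@dataclass
class BorderPath:
    """Traced LZ–JZ border: one or more 8-connected pixel chains."""

    points: np.ndarray  # (N, 2) as (x, y); concatenation of all pieces
    closed: bool  # single piece forming a loop
    length: float  # physical units (pixel_size applied)
    pieces: list = field(default_factory=list)  # [(points, closed), ...]

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0


@dataclass
class SectionMeasurements:
    """The per-section quantities, in ``pixel_size``² / ``pixel_size``
    units (px²/px when uncalibrated)."""

    image_id: str
    total_area: float
    lz_area: float
    jz_area: float
    decidua_area: float
    lz_tissue_pct: float
    jz_tissue_pct: float
    decidua_tissue_pct: float
    border_length: float
    tortuosity: float
    excluded_area: float
    pixel_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    def zone_areas(self) -> dict[str, float]:
        return {"LZ": self.lz_area, "JZ": self.jz_area,
                "decidua": self.decidua_area}

    def tissue_pcts(self) -> dict[str, float]:
        return {"LZ": self.lz_tissue_pct, "JZ": self.jz_tissue_pct,
                "decidua": self.decidua_tissue_pct}


# ---------------------------------------------------------------------------
# Polygon rasterization


def _clean_polygon(vertices: np.ndarray) -> list[np.ndarray]:
    """Distinct-vertex check + self-intersection repair via shapely.

    Returns one or more simple rings to rasterize (a self-touching
    input may clean into several)."""
    distinct = np.unique(vertices, axis=0)
    if len(distinct) < 3:
        raise ValueError(
            f"polygon needs >= 3 distinct vertices, got {len(distinct)}"
        )
    poly = Polygon(vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0.0:
        return []
    if isinstance(poly, MultiPolygon):
        return [np.asarray(g.exterior.coords) for g in poly.geoms]
    return [np.asarray(poly.exterior.coords)]


def _rasterize_even_odd(verts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd crossing-number rasterization at pixel centers.

    Scanline over each edge's row span; the crossing comparison is
    division-free (cross-multiplied), and pixel centers within float
    noise of an edge are resolved with exact rational arithmetic, so a
    center is classified exactly as the ideal even-odd rule dictates.
    """
    from fractions import Fraction

    h, w = shape
    xs = np.arange(w) + 0.5
    crossings = np.zeros((h, w), dtype=np.int32)
    n = len(verts)
    for k in range(n):
        x1, y1 = float(verts[k, 0]), float(verts[k, 1])
        x2, y2 = float(verts[(k + 1) % n, 0]), float(verts[(k + 1) % n, 1])
        if y1 == y2:
            continue
        ylo, yhi = (y1, y2) if y1 < y2 else (y2, y1)
        i0 = max(0, int(np.ceil(ylo - 0.5)))
        i1 = min(h - 1, int(np.floor(yhi - 0.5)))
        for i in range(i0, i1 + 1):
            y = i + 0.5
            if (y1 > y) == (y2 > y):
                continue
            # crossing to the right of x  ⟺  x < x1 + (y−y1)(x2−x1)/(y2−y1)
            lhs = (xs - x1) * (y2 - y1)
            rhs = (y - y1) * (x2 - x1)
            t = lhs - rhs
            crosses = (t < 0) if y2 > y1 else (t > 0)
            near = np.abs(t) <= 1e-9 * (np.abs(lhs) + abs(rhs) + 1.0)
            if near.any():
                fy = (Fraction(y) - Fraction(y1)) \
                    * (Fraction(x2) - Fraction(x1))
                fdy = Fraction(y2) - Fraction(y1)
                for j in np.nonzero(near)[0]:
                    ft = (Fraction(xs[j]) - Fraction(x1)) * fdy - fy
                    crosses[j] = (ft < 0) if y2 > y1 else (ft > 0)
            crossings[i] += crosses
    return (crossings % 2).astype(bool)


def outline_to_mask(
    outline: ZoneOutline, shape: tuple[int, int], clip: bool = True
) -> np.ndarray:
    """Rasterize an outline: pixel centers inside the polygon (even-odd).

    Vertices may extend past the raster; with ``clip`` the mask is
    confined to the raster (warning), otherwise that is an error.
    """
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("raster shape must be at least 1x1")
    verts = outline.polygon
    out_of_bounds = (
        (verts[:, 0] < 0).any() or (verts[:, 0] > w).any()
        or (verts[:, 1] < 0).any() or (verts[:, 1] > h).any()
    )
    if out_of_bounds:
        if not clip:
            raise ValueError(
                f"outline for zone {outline.zone!r} extends past the raster "
                "and clip is disabled"
            )
        warnings.warn(
            f"outline for zone {outline.zone!r} extends past the raster; "
            "mask clipped",
            stacklevel=2,
        )
    rings = _clean_polygon(verts)
    if not rings:
        warnings.warn(
            f"outline for zone {outline.zone!r} has zero area; empty mask",
            stacklevel=2,
        )
        return np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    for ring in rings:
        mask |= _rasterize_even_odd(np.asarray(ring, dtype=float), shape)
    return mask


# ---------------------------------------------------------------------------
# Areas and tissue fractions


def zone_area(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Pixel-count area: |mask| × pixel_size²."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        warnings.warn("zone mask is empty; area is 0", stacklevel=2)
    return n * pixel_size**2


def tissue_fraction(
    mask: np.ndarray, background: np.ndarray, pixel_size: float = 1.0
) -> tuple[float, float]:
    """Percent of a zone occupied by tissue, and the tissue-only area.

    Background pixels inside the zone (lumens, holes, tissue-free
    space) are subtracted: pct = 100·(1 − |mask ∧ bg| / |mask|).
    """
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("tissue fraction is undefined for an empty mask")
    n_bg = int(np.count_nonzero(mask & background))
    pct = 100.0 * (1.0 - n_bg / n)
    tissue_area = (n - n_bg) * pixel_size**2
    return pct, tissue_area


# ---------------------------------------------------------------------------
# Border extraction


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """True pixels 4-adjacent to a false pixel or the image edge."""
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def _trace_component(coords: set[tuple[int, int]]) -> list[tuple[list, bool]]:
    """Order an 8-connected pixel set into chains.

    Marching starts at a degree-1 endpoint when one exists (open
    chain), else at the lexicographically smallest pixel (loop).
    Greedy walk preferring 4-neighbors; leftover pixels (thick clumps)
    start extra chains.  Deterministic.
    """
    nbrs8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    nbrs4 = {(-1, 0), (0, -1), (0, 1), (1, 0)}

    def neighbors(p, pool):
        return [(p[0] + d[0], p[1] + d[1]) for d in nbrs8
                if (p[0] + d[0], p[1] + d[1]) in pool]

    remaining = set(coords)
    chains: list[tuple[list, bool]] = []
    while remaining:
        degree = {p: len(neighbors(p, remaining)) for p in remaining}
        endpoints = sorted(p for p, d in degree.items() if d <= 1)
        start = endpoints[0] if endpoints else min(remaining)
        was_loop_candidate = not endpoints
        chain = [start]
        remaining.discard(start)
        cur = start
        while True:
            cand = neighbors(cur, remaining)
            if not cand:
                break
            # prefer lateral moves, then lexicographic, for determinism
            cand.sort(key=lambda q: (
                (q[0] - cur[0], q[1] - cur[1]) not in nbrs4, q))
            cur = cand[0]
            chain.append(cur)
            remaining.discard(cur)
        closed = (
            was_loop_candidate
            and len(chain) > 2
            and max(abs(chain[0][0] - chain[-1][0]),
                    abs(chain[0][1] - chain[-1][1])) == 1
        )
        chains.append((chain, closed))
    return chains


def _chain_length(chain: list, closed: bool, step: int) -> float:
    """Polyline length through every ``step``-th pixel of a chain.

    Resampling removes the ~5% overestimate a raw lateral/diagonal
    chain sum carries on smooth digitized curves; straight axis-aligned
    chains are measured exactly.
    """
    pts = np.asarray(chain, dtype=float)
    if len(pts) < 2:
        return 0.0
    idx = list(range(0, len(pts), max(1, step)))
    if idx[-1] != len(pts) - 1:
        idx.append(len(pts) - 1)
    sampled = pts[idx]
    if closed:
        sampled = np.vstack([sampled, sampled[:1]])
    return float(np.sqrt(np.diff(sampled, axis=0) ** 2@np.ones(2)).sum())


def lz_jz_border(
    lz: np.ndarray,
    jz: np.ndarray,
    adjacency_tol: float = math.sqrt(2),
    pixel_size: float = 1.0,
    resample_step: int = 5,
) -> BorderPath:
    """Shared LZ–JZ border: where the two zones' perimeters overlap.

    LZ boundary pixels within ``adjacency_tol`` of a JZ boundary pixel
    form the border; each 8-connected component is ordered by marching
    and measured as a resampled polyline; lengths of all components are
    summed and scaled by ``pixel_size``.
    """
    if lz.shape != jz.shape:
        raise ValueError("masks must share a shape")
    empty = BorderPath(points=np.empty((0, 2)), closed=False, length=0.0)
    b_lz = _boundary_pixels(lz)
    b_jz = _boundary_pixels(jz)
    if len(b_lz) == 0 or len(b_jz) == 0:
        warnings.warn("one of the masks has no boundary; empty border",
                      stacklevel=2)
        return empty
    tree_jz = cKDTree(b_jz)
    dist, _ = tree_jz.query(b_lz)
    border_lz = b_lz[dist <= adjacency_tol + 1e-9]
    if len(border_lz) == 0:
        warnings.warn(
            "LZ and JZ boundaries are farther apart than the adjacency "
            "tolerance; border length 0",
            stacklevel=2,
        )
        return empty
    dist_jz, _ = cKDTree(b_lz).query(b_jz)
    border_jz = b_jz[dist_jz <= adjacency_tol + 1e-9]

    def trace_side(border):
        border_mask = np.zeros(lz.shape, dtype=bool)
        border_mask[border[:, 0], border[:, 1]] = True
        comp_labels, n_comp = ndimage.label(border_mask, structure=_BOX)
        pieces: list[tuple[np.ndarray, bool]] = []
        total = 0.0
        for c in range(1, n_comp + 1):
            coords = {tuple(p) for p in np.argwhere(comp_labels == c)}
            for chain, closed in _trace_component(coords):
                total += _chain_length(chain, closed, resample_step)
                pts_xy = np.asarray(
                    [(col, row) for row, col in chain], dtype=float)
                pieces.append((pts_xy, closed))
        return total, pieces

    # the true interface lies between the two pixel fronts: average the
    # two one-sided trace lengths (symmetric in the arguments, and
    # cancels the half-pixel inside/outside bias)
    total_lz, pieces = trace_side(border_lz)
    total_jz, _ = trace_side(border_jz)
    total = (total_lz + total_jz) / 2.0
    points = (np.vstack([p for p, _ in pieces]) if pieces
              else np.empty((0, 2)))
    closed = len(pieces) == 1 and pieces[0][1]
    return BorderPath(points=points, closed=closed,
                      length=total * pixel_size, pieces=pieces)


def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polyline (absolute value)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def border_tortuosity(path: BorderPath, enclosed_area: float | None = None) -> float:
    """Path length relative to the smoothest curve with the same ends.

    Open paths: length / chord (endpoint distance).  Closed paths:
    length / perimeter of the circle with the same enclosed area,
    2·sqrt(π·area).  Both are ≥ 1 up to discretization error; 1 means
    perfectly smooth.
    """
    if path.is_empty:
        raise ValueError("tortuosity is undefined for an empty border")
    if path.closed:
        if enclosed_area is None:
            raise ValueError("closed path requires enclosed_area")
        if enclosed_area <= 0:
            raise ValueError("enclosed_area must be positive")
        return path.length / (2.0 * math.sqrt(math.pi * enclosed_area))
    # use the longest piece's endpoints for the chord
    pts = max(path.pieces, key=lambda pc: len(pc[0]))[0] if path.pieces \
        else path.points
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        raise ValueError("open path with zero chord")
    return path.length / chord


# ---------------------------------------------------------------------------
# Zone classification (outlines × segmentation → masks)


def _zone_label_raster(
    hsv,
    outline_masks: dict[str, np.ndarray],
    segment_labels: np.ndarray,
    assignment: ZoneAssignment,
    background: np.ndarray,
    weights: tuple[float, float, float],
) -> np.ndarray:
    """Per-pixel zone index (−1 = none), combining three rules.

    1. A tissue pixel whose HSV segment is owned by a zone joins that
       zone, provided the zone's outline contains the pixel.
    2. Any other tissue pixel inside ≥ 1 outline joins the candidate
       zone whose reference stain color is nearest (weighted circular
       HSV distance; the hue term is dropped for unsaturated pixels).
    3. Background pixels NOT connected to the image border (holes and
       tissue-free space inside the section) join the zone of the
       geometrically nearest classified tissue pixel among their
       candidate outlines; border-connected background is exterior and
       belongs to no zone.
    """
    shape = background.shape
    n_zone = len(ZONES)

    # segment → owning zone index (−1 when unowned / shared loser)
    n_segments = int(segment_labels.max()) + 1 if segment_labels.max() >= 0 else 0
    seg_owner = np.full(max(n_segments, 1), -1, dtype=np.int32)
    for seg in range(n_segments):
        owner = assignment.owner_of_segment(seg)
        if owner is not None:
            seg_owner[seg] = ZONES.index(owner)
    owner_px = np.full(shape, -1, dtype=np.int32)
    in_ref = segment_labels >= 0
    owner_px[in_ref] = seg_owner[segment_labels[in_ref]]

    # weighted color distance of every pixel to every zone reference
    pix = np.stack([hsv.h, hsv.s, hsv.v], axis=-1)
    dist = np.empty((n_zone,) + shape)
    w_h, w_s, w_v = weights
    for zi, zone in enumerate(ZONES):
        ref = np.asarray(assignment.zone_refs[zone], dtype=float)
        d = hsv_color_distance(pix, ref[None, None, :], weights=weights)
        # hue undefined: drop the hue term rather than trust stored 0
        und = hsv.undefined_hue
        if und.any():
            ds = hsv.s[und] - ref[1]
            dv = hsv.v[und] - ref[2]
            d[und] = np.sqrt(w_s * ds**2 + w_v * dv**2)
        dist[zi] = d

    tissue = ~background
    score = np.full((n_zone,) + shape, np.inf)
    for zi, zone in enumerate(ZONES):
        inside = outline_masks[zone]
        sel = inside & tissue
        score[zi][sel] = dist[zi][sel]
        claimed = sel & (owner_px == zi)
        score[zi][claimed] = -1.0  # segmentation overrides color distance

    zone_label = np.full(shape, -1, dtype=np.int32)
    best = score.min(axis=0)
    has_zone = np.isfinite(best)
    zone_label[has_zone] = np.argmin(score, axis=0)[has_zone]

    # enclosed background → nearest classified tissue pixel's zone
    bg_comp, _ = ndimage.label(background, structure=_CROSS)
    edge_ids = np.unique(np.concatenate([
        bg_comp[0, :], bg_comp[-1, :], bg_comp[:, 0], bg_comp[:, -1]]))
    exterior = np.isin(bg_comp, edge_ids[edge_ids > 0])
    enclosed = background & ~exterior
    any_outline = np.zeros(shape, dtype=bool)
    for zone in ZONES:
        any_outline |= outline_masks[zone]
    holes = enclosed & any_outline
    if holes.any() and (zone_label >= 0).any():
        assigned = zone_label >= 0
        _, (ir, ic) = ndimage.distance_transform_edt(
            ~assigned, return_indices=True)
        nearest = zone_label[ir, ic]
        hole_zone = nearest[holes]
        # keep only assignments whose outline actually contains the hole
        rows, cols = np.nonzero(holes)
        ok = np.zeros(len(rows), dtype=bool)
        for zi, zone in enumerate(ZONES):
            ok |= (hole_zone == zi) & outline_masks[zone][rows, cols]
        # fallback: first containing outline in ZONES order
        if (~ok).any():
            fb = np.full(len(rows), -1, dtype=np.int32)
            for zi in range(n_zone - 1, -1, -1):
                zin = outline_masks[ZONES[zi]][rows, cols]
                fb[zin] = zi
            hole_zone = np.where(ok, hole_zone, fb)
        zone_label[rows, cols] = hole_zone
    return zone_label


# ---------------------------------------------------------------------------
# The per-section pipeline


@dataclass
class SectionContext:
    """Everything needed to (re)compute measurements for one section."""

    image_id: str
    pixel_size: float
    zone_masks: dict[str, np.ndarray]
    background: np.ndarray
    exclusion: np.ndarray  # accumulated exclusion raster
    adjacency_tol: float = math.sqrt(2)
    resample_step: int = 5
    provenance: dict = field(default_factory=dict)


def _measure_from_context(ctx: SectionContext) -> SectionMeasurements:
    ps = ctx.pixel_size
    keep = ~ctx.exclusion
    masks = {z: ctx.zone_masks[z] & keep for z in ZONES}
    areas: dict[str, float] = {}
    pcts: dict[str, float] = {}
    for zone in ZONES:
        n = int(np.count_nonzero(masks[zone]))
        areas[zone] = n * ps**2
        if n == 0:
            warnings.warn(f"zone {zone} has no pixels left", stacklevel=2)
            pcts[zone] = float("nan")
        else:
            pcts[zone], _ = tissue_fraction(masks[zone], ctx.background, ps)
    union = np.zeros_like(keep)
    for zone in ZONES:
        union |= ctx.zone_masks[zone]
    total_area = int(np.count_nonzero(union & keep)) * ps**2
    excluded_area = int(np.count_nonzero(union & ctx.exclusion)) * ps**2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = lz_jz_border(masks["LZ"], masks["JZ"],
                            adjacency_tol=ctx.adjacency_tol,
                            pixel_size=ps,
                            resample_step=ctx.resample_step)
    if path.is_empty:
        tort = float("nan")
    elif path.closed:
        tort = border_tortuosity(
            path, enclosed_area=polygon_area(path.points) * ps**2)
    else:
        tort = border_tortuosity(path)

    return SectionMeasurements(
        image_id=ctx.image_id,
        total_area=total_area,
        lz_area=areas["LZ"],
        jz_area=areas["JZ"],
        decidua_area=areas["decidua"],
        lz_tissue_pct=pcts["LZ"],
        jz_tissue_pct=pcts["JZ"],
        decidua_tissue_pct=pcts["decidua"],
        border_length=path.length,
        tortuosity=tort,
        excluded_area=excluded_area,
        pixel_size=ps,
        provenance=dict(ctx.provenance),
    )


def apply_exclusion(
    ctx: SectionContext, exclusions: list[np.ndarray]
) -> tuple[SectionContext, SectionMeasurements]:
    """Remove operator-marked regions and recompute all quantities.

    Each exclusion is a polygon vertex array; the union of their
    rasters is removed from every zone mask and the total-area mask.
    An exclusion disjoint from all zones changes nothing.
    """
    excl = ctx.exclusion.copy()
    shape = ctx.background.shape
    for poly in exclusions:
        outline = ZoneOutline(zone="exclusion", polygon=np.asarray(poly))
        excl |= outline_to_mask(outline, shape, clip=True)
    new_ctx = SectionContext(
        image_id=ctx.image_id,
        pixel_size=ctx.pixel_size,
        zone_masks=ctx.zone_masks,
        background=ctx.background,
        exclusion=excl,
        adjacency_tol=ctx.adjacency_tol,
        resample_step=ctx.resample_step,
        provenance=ctx.provenance,
    )
    return new_ctx, _measure_from_context(new_ctx)


def measure_section(
    image: RasterImage,
    session,
    config=None,
    return_context: bool = False,
):
    """Run the full pipeline on one section.

    normalize → CMYK k-means → reference-cluster choice → HSV peak
    segmentation → zone assignment → zone masks (outline × segment ×
    tissue rules) → areas, tissue fractions, border, tortuosity →
    exclusions.  Deterministic for a fixed config seed.

    ``session`` supplies the formerly interactive choices (reference
    cluster or "auto", one outline per zone, optional exclusion
    polygons, optional zone-color overrides); ``config`` the tunables.
    """
    from .config import RunConfig  # local import: config is pure-data

    cfg = config if config is not None else RunConfig()

    for zone in ZONES:
        if zone not in session.zone_outlines:
            raise ValueError(f"session is missing an outline for zone {zone}")

    # the contrast stretch controls stain intensity for the clustering
    # stage; color-reference comparisons use the raw stain colors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = normalize_intensity(image, cfg.norm_low_pct, cfg.norm_high_pct)
    hsv = rgb_to_hsv(image)
    cmyk = rgb_to_cmyk(norm)
    clusters = cluster_cmyk(
        cmyk, k=cfg.k_clusters, seed=cfg.seed, max_iter=cfg.kmeans_max_iter,
        bg_v_min=cfg.bg_v_min, bg_s_max=cfg.bg_s_max)
    if session.cluster_index == "auto":
        ref = select_reference_cluster(clusters, mode="auto",
                                       min_frac=cfg.ref_min_frac)
    else:
        ref = select_reference_cluster(
            clusters, mode="manual", cluster_index=int(session.cluster_index))
    bg = background_mask(hsv, v_min=cfg.bg_v_min, s_max=cfg.bg_s_max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        segments = hsv_peak_segments(
            hsv, clusters.labels == ref, n_peaks=cfg.n_peaks,
            bins=cfg.hue_bins, min_separation=cfg.peak_min_separation,
            s_floor=cfg.s_floor)
        zone_refs = session.zone_refs or cfg.zone_refs
        assignment = assign_zone_segment(segments, zone_refs,
                                         weights=cfg.color_weights)

    shape = image.shape
    outline_masks = {}
    for zone in ZONES:
        outline = ZoneOutline(zone=zone,
                              polygon=session.zone_outlines[zone])
        outline_masks[zone] = outline_to_mask(outline, shape, clip=True)

    if cfg.mask_rule == "outline":
        # outline-only: overlaps resolved in fixed LZ > JZ > decidua order
        zone_label = np.full(shape, -1, dtype=np.int32)
        for zi in range(len(ZONES) - 1, -1, -1):
            zone_label[outline_masks[ZONES[zi]]] = zi
    else:
        zone_label = _zone_label_raster(
            hsv, outline_masks, segments.labels, assignment, bg,
            cfg.color_weights)

    zone_masks = {z: zone_label == zi for zi, z in enumerate(ZONES)}

    ctx = SectionContext(
        image_id=image.id,
        pixel_size=image.pixel_size,
        zone_masks=zone_masks,
        background=bg,
        exclusion=np.zeros(shape, dtype=bool),
        adjacency_tol=cfg.adjacency_tol,
        resample_step=cfg.border_resample_step,
        provenance={
            "session_hash": session.digest(),
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "reference_cluster": ref,
        },
    )
    ctx, meas = apply_exclusion(ctx, session.exclusions)
    if return_context:
        return meas, ctx
    return meas
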