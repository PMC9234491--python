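"""Two-stage color segmentation of H&E placental sections.

Stage one clusters pixels into eight groups in CMYK space (k-means) and
picks a reference cluster — the one brightest across the placental
zones.  Stage two segments the reference cluster by peaks of a
saturation-weighted circular hue histogram, then assigns each placental
zone (labyrinth LZ, junctional JZ, decidua) to the segment whose peak
color is nearest that zone's characteristic stain color.  A simple
value/saturation threshold separates tissue from background (unstained
slide, lumens, holes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .colorspace import CMYKPlanes, HSVPlanes

__all__ = [
    "ZONES",
    "ClusterMap",
    "SegmentMap",
    "ZoneAssignment",
    "cluster_cmyk",
    "select_reference_cluster",
    "hsv_peak_segments",
    "assign_zone_segment",
    "background_mask",
    "circular_hue_distance",
    "hsv_color_distance",
    "DEFAULT_ZONE_REFS",
]

#: Zone labels, in fixed order (labyrinth, junctional, decidua).
ZONES = ("LZ", "JZ", "decidua")

#: Default zone reference stain colors in HSV (documented defaults for
#: H&E: eosin-pink labyrinth, purple junctional zone, dark violet
#: decidua); override per session or config.
DEFAULT_ZONE_REFS = {
    "LZ": (0.97, 0.45, 0.85),
    "JZ": (0.78, 0.55, 0.55),
    "decidua": (0.72, 0.50, 0.35),
}


@dataclass
class ClusterMap:
    """Result of CMYK k-means clustering.

    ``labels`` is H×W with values in {0..k−1} (−1 for masked-out
    pixels); ``mean_brightness`` is the mean HSV value per cluster
    (V = 1 − K, so it is computable from CMYK alone);
    ``background_fraction`` is the fraction of each cluster's pixels
    that look like unstained background.
    """

    labels: np.ndarray
    centroids: np.ndarray
    member_counts: np.ndarray
    mean_brightness: np.ndarray
    background_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.background_fraction is None:
            self.background_fraction = np.zeros(len(self.member_counts))

    @property
    def k(self) -> int:
        return len(self.member_counts)


@dataclass
class SegmentMap:
    """HSV peak segmentation of the reference cluster.

    ``labels`` is H×W in {0..n−1}, −1 outside the reference cluster;
    ``peak_colors`` are the per-segment mean HSV colors (circular mean
    for hue); ``peak_hues`` the histogram-peak hues the assignment used.
    """

    labels: np.ndarray
    peak_colors: np.ndarray
    peak_hues: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.peak_colors)


@dataclass
class ZoneAssignment:
    """zone → segment index, with the distances that justified it."""

    zone_to_segment: dict[str, int]
    distances: dict[str, float]
    zone_refs: dict[str, tuple[float, float, float]]

    def owner_of_segment(self, seg: int) -> str | None:
        """The zone a segment belongs to (nearest zone if shared)."""
        owners = [z for z, s in self.zone_to_segment.items() if s == seg]
        if not owners:
            return None
        return min(owners, key=lambda z: self.distances[z])


def circular_hue_distance(h1, h2):
    """Shortest distance on the hue circle (0 ≡ 1)."""
    d = np.abs(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float))
    return np.minimum(d, 1.0 - d)


def hsv_color_distance(hsv_a, hsv_b, weights=(2.0, 1.0, 1.0)):
    """Weighted HSV distance sqrt(w_h·Δh_circ² + w_s·Δs² + w_v·Δv²).

    ``hsv_a``/``hsv_b`` are (..., 3) arrays; broadcastable.
    """
    a = np.asarray(hsv_a, dtype=float)
    b = np.asarray(hsv_b, dtype=float)
    dh = circular_hue_distance(a[..., 0], b[..., 0])
    ds = a[..., 1] - b[..., 1]
    dv = a[..., 2] - b[..., 2]
    w_h, w_s, w_v = weights
    return np.sqrt(w_h * dh**2 + w_s * ds**2 + w_v * dv**2)


def cluster_cmyk(
    planes: CMYKPlanes,
    k: int = 8,
    seed: int = 0,
    max_iter: int = 100,
    fit_subsample: int = 200_000,
    bg_v_min: float = 0.92,
    bg_s_max: float = 0.12,
) -> ClusterMap:
    """Seeded k-means partition of pixels in 4-D CMYK space.

    Deterministic for a fixed seed.  Centroids are fit on a seeded
    subsample when the image exceeds ``fit_subsample`` pixels and every
    pixel is then assigned to its nearest centroid.  Clusters may end up
    empty (reported with a warning), e.g. when the image holds fewer
    distinct colors than ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    features = planes.stack()
    n = features.shape[0]
    if n == 0:
        raise ValueError("empty image: nothing to cluster")

    rng = np.random.default_rng(seed)
    if n > fit_subsample:
        idx = rng.choice(n, size=fit_subsample, replace=False)
        fit_data = features[idx]
    else:
        fit_data = features

    n_fit_clusters = min(k, fit_data.shape[0])
    km = KMeans(
        n_clusters=n_fit_clusters,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
        algorithm="lloyd",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km.fit(fit_data)
    labels_flat = km.predict(features)

    centroids = np.zeros((k, 4))
    centroids[:n_fit_clusters] = km.cluster_centers_
    member_counts = np.bincount(labels_flat, minlength=k)
    if (member_counts == 0).any():
        warnings.warn(
            f"{int((member_counts == 0).sum())} of {k} CMYK clusters are "
            "empty (fewer distinct colors than clusters?)",
            stacklevel=2,
        )

    # V = max(R,G,B) = 1 − K; S = max(C,M,Y) when V > 0.
    v = 1.0 - features[:, 3]
    s = features[:, :3].max(axis=1)
    is_bg = (v >= bg_v_min) & (s <= bg_s_max)
    mean_brightness = np.zeros(k)
    background_fraction = np.zeros(k)
    for c in range(k):
        sel = labels_flat == c
        if sel.any():
            mean_brightness[c] = v[sel].mean()
            background_fraction[c] = is_bg[sel].mean()

    return ClusterMap(
        labels=labels_flat.reshape(planes.shape).astype(np.int32),
        centroids=centroids,
        member_counts=member_counts,
        mean_brightness=mean_brightness,
        background_fraction=background_fraction,
    )


def select_reference_cluster(
    clusters: ClusterMap,
    mode: str = "auto",
    cluster_index: int | None = None,
    min_frac: float = 0.01,
    bg_max_frac: float = 0.5,
) -> int:
    """Pick the CMYK cluster the HSV segmentation will operate on.

    Manual mode returns the supplied index verbatim (the choice a user
    of the original interactive script would have typed).  Auto mode
    returns the cluster with the highest mean brightness among clusters
    holding at least ``min_frac`` of the labeled pixels, skipping
    clusters dominated by unstained background (fraction ≥
    ``bg_max_frac``) — background is bright but is not a placental
    zone.
    """
    if mode == "manual":
        if cluster_index is None:
            raise ValueError("manual mode requires a cluster index")
        if not (0 <= cluster_index < clusters.k):
            raise ValueError(
                f"cluster index {cluster_index} out of range [0, {clusters.k})"
            )
        if clusters.member_counts[cluster_index] == 0:
            raise ValueError(f"cluster {cluster_index} is empty")
        return int(cluster_index)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    total = clusters.member_counts.sum()
    eligible = clusters.member_counts > min_frac * total
    candidates = eligible & (clusters.background_fraction < bg_max_frac)
    if not candidates.any():
        candidates = eligible  # all tissue-like excluded: fall back
    if not candidates.any():
        raise ValueError(
            f"no cluster holds more than {min_frac:.0%} of the pixels"
        )
    brightness = np.where(candidates, clusters.mean_brightness, -np.inf)
    return int(np.argmax(brightness))


def _circular_peak_bins(
    hist: np.ndarray, n_peaks: int, min_separation: int
) -> list[int]:
    """Local maxima of a circular histogram, tallest first, at least
    ``min_separation`` bins apart (circularly)."""
    bins = len(hist)
    left = np.roll(hist, 1)
    right = np.roll(hist, -1)
    is_max = (hist > 0) & (hist >= left) & (hist > right)
    order = [int(i) for i in np.argsort(hist, kind="stable")[::-1] if is_max[i]]
    kept: list[int] = []
    for i in order:
        if len(kept) >= n_peaks:
            break
        sep = [min(abs(i - j), bins - abs(i - j)) for j in kept]
        if all(s >= min_separation for s in sep):
            kept.append(i)
    return kept


def hsv_peak_segments(
    hsv: HSVPlanes,
    within: np.ndarray,
    n_peaks: int = 8,
    bins: int = 64,
    min_separation: int = 2,
    s_floor: float = 0.05,
) -> SegmentMap:
    """Segment ``within``-pixels by peaks of the circular hue histogram.

    The histogram is built over saturated within-pixels (S ≥
    ``s_floor``) weighted by saturation; up to ``n_peaks`` local maxima
    at circular separation ≥ ``min_separation`` bins become segment
    seeds, and every within-pixel is labeled with the circularly
    nearest peak hue.  If no within-pixel is saturated a single segment
    is returned with a warning.
    """
    within = np.asarray(within, dtype=bool)
    if not within.any():
        raise ValueError("'within' selects no pixels")

    h = hsv.h[within]
    s = hsv.s[within]
    saturated = s >= s_floor

    labels = np.full(hsv.shape, -1, dtype=np.int32)
    if not saturated.any():
        warnings.warn(
            "all pixels in the reference region are unsaturated; "
            "returning a single segment",
            stacklevel=2,
        )
        labels[within] = 0
        mean_hsv = np.array([[0.0, s.mean(), hsv.v[within].mean()]])
        return SegmentMap(labels=labels, peak_colors=mean_hsv,
                          peak_hues=np.array([0.0]))

    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(h[saturated], bins=edges, weights=s[saturated])
    peak_bins = _circular_peak_bins(hist, n_peaks, min_separation)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak_hues = centers[peak_bins] if peak_bins else np.array([h[saturated][0]])

    # nearest peak by circular hue distance, per within-pixel
    d = circular_hue_distance(h[:, None], peak_hues[None, :])
    assign = np.argmin(d, axis=1)
    labels[within] = assign

    n = len(peak_hues)
    peak_colors = np.zeros((n, 3))
    v = hsv.v[within]
    for seg in range(n):
        sel = assign == seg
        sel_sat = sel & saturated
        if sel_sat.any():
            ang = 2 * np.pi * h[sel_sat]
            w = s[sel_sat]
            mean_ang = np.arctan2((w * np.sin(ang)).sum(),
                                  (w * np.cos(ang)).sum())
            peak_colors[seg, 0] = (mean_ang / (2 * np.pi)) % 1.0
        if sel.any():
            peak_colors[seg, 1] = s[sel].mean()
            peak_colors[seg, 2] = v[sel].mean()
    return SegmentMap(labels=labels, peak_colors=peak_colors,
                      peak_hues=np.asarray(peak_hues, dtype=float))


def assign_zone_segment(
    segments: SegmentMap,
    zone_refs: dict[str, tuple[float, float, float]] | None = None,
    weights: tuple[float, float, float] = (2.0, 1.0, 1.0),
) -> ZoneAssignment:
    """Map each placental zone to the segment nearest its stain color.

    Distance is the weighted circular-HSV metric; ties go to the lowest
    segment index (warning), and two zones may legitimately share a
    segment (warning) when the reference cluster does not span all
    stain colors.
    """
    if zone_refs is None:
        zone_refs = DEFAULT_ZONE_REFS
    non_empty = [
        seg for seg in range(segments.n_segments)
        if (segments.labels == seg).any()
    ]
    if not non_empty:
        raise ValueError("SegmentMap has no non-empty segments")

    zone_to_segment: dict[str, int] = {}
    distances: dict[str, float] = {}
    for zone in ZONES:
        ref = np.asarray(zone_refs[zone], dtype=float)
        d = hsv_color_distance(
            segments.peak_colors[non_empty], ref[None, :], weights=weights
        )
        best = float(d.min())
        hits = [non_empty[i] for i in range(len(non_empty))
                if np.isclose(d[i], best, rtol=0, atol=1e-12)]
        if len(hits) > 1:
            warnings.warn(
                f"zone {zone}: segments {hits} equidistant from reference "
                "color; taking the lowest index",
                stacklevel=2,
            )
        zone_to_segment[zone] = hits[0]
        distances[zone] = best

    seen: dict[int, str] = {}
    for zone, seg in zone_to_segment.items():
        if seg in seen:
            warnings.warn(
                f"zones {seen[seg]} and {zone} both map to segment {seg}",
                stacklevel=2,
            )
        else:
            seen[seg] = zone
    return ZoneAssignment(zone_to_segment=zone_to_segment,
                          distances=distances,
                          zone_refs={z: tuple(zone_refs[z]) for z in ZONES})


def background_mask(
    hsv: HSVPlanes, v_min: float = 0.92, s_max: float = 0.12
) -> np.ndarray:
    """Pixels that carry no tissue: bright (V ≥ v_min) and unstained
    (S ≤ s_max).  The tissue mask is the complement."""
    if not (0.0 <= v_min <= 1.0 and 0.0 <= s_max <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    return (hsv.v >= v_min) & (hsv.s <= s_max)
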