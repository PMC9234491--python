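"""Masks, areas, border tracing and tortuosity against geometric oracles."""

import math
import warnings

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from zonemetrics import (
    BorderPath,
    RunConfig,
    ZoneOutline,
    apply_exclusion,
    border_tortuosity,
    lz_jz_border,
    measure_section,
    outline_to_mask,
    tissue_fraction,
    zone_area,
)
from zonemetrics.morphometry import polygon_area
from zonemetrics.phantom import PhantomSpec, generate_phantom, \
    make_session_from_truth
from zonemetrics.segmentation import ZONES


def star_polygon(rng, n_vertices, shape):
    """Random simple (star-shaped) polygon inside a raster.

    All consecutive angular gaps are kept below π, which guarantees the
    polygon is simple for any radii."""
    h, w = shape
    cx = rng.uniform(0.3 * w, 0.7 * w)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    while True:
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        if gaps.max() < np.pi:
            break
    rad = rng.uniform(0.1, 0.45) * min(h, w) * rng.uniform(0.4, 1.0, n_vertices)
    return np.stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)], axis=1)


def shapely_raster_oracle(vertices, shape):
    """Independent rasterization: shapely point-in-polygon per center."""
    poly = Polygon(vertices)
    mask = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            mask[i, j] = poly.contains(Point(j + 0.5, i + 0.5))
    return mask


def cross_pair_count(a, b):
    """Number of 4-adjacent (a-pixel, b-pixel) pairs."""
    n = 0
    n += np.count_nonzero(a[:, :-1] & b[:, 1:])
    n += np.count_nonzero(a[:, 1:] & b[:, :-1])
    n += np.count_nonzero(a[:-1, :] & b[1:, :])
    n += np.count_nonzero(a[1:, :] & b[:-1, :])
    return n


class TestOutlineToMask:
    def test_axis_aligned_square_pixel_count(self):
        outline = ZoneOutline("LZ", [(0, 0), (10, 0), (10, 10), (0, 10)])
        mask = outline_to_mask(outline, (20, 20))
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_matches_shapely_oracle_on_random_polygons(self, rng):
        for _ in range(20):
            verts = star_polygon(rng, int(rng.integers(3, 10)), (32, 32))
            mask = outline_to_mask(ZoneOutline("LZ", verts), (32, 32))
            assert np.array_equal(mask, shapely_raster_oracle(verts, (32, 32)))

    def test_two_vertex_polygon_is_error(self):
        with pytest.raises(ValueError, match="3 distinct"):
            outline_to_mask(ZoneOutline("LZ", [(0, 0), (5, 5), (0, 0)]),
                            (10, 10))

    def test_clipping_contract(self):
        outline = ZoneOutline("LZ", [(-5, -5), (15, -5), (15, 15), (-5, 15)])
        with pytest.warns(UserWarning, match="clipped"):
            mask = outline_to_mask(outline, (10, 10), clip=True)
        assert mask.all()
        with pytest.raises(ValueError, match="clip"):
            outline_to_mask(outline, (10, 10), clip=False)

    def test_zero_area_polygon_empty_mask_with_warning(self):
        outline = ZoneOutline("LZ", [(1, 1), (5, 5), (9, 9)])
        with pytest.warns(UserWarning, match="zero area"):
            mask = outline_to_mask(outline, (12, 12))
        assert not mask.any()


class TestAreasAndTissue:
    def test_area_scales_with_pixel_size(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True
        assert zone_area(mask) == 100
        assert zone_area(mask, pixel_size=2.0) == 400.0

    def test_empty_mask_area_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            assert zone_area(np.zeros((5, 5), dtype=bool)) == 0

    def test_tissue_fraction_arithmetic(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask.ravel()[:1000] = True
        bg = np.zeros_like(mask)
        bg.ravel()[:50] = True
        pct, tissue_area = tissue_fraction(mask, bg)
        assert pct == pytest.approx(95.0)
        assert tissue_area == 950
        assert tissue_fraction(mask, np.zeros_like(mask))[0] == 100.0

    def test_tissue_fraction_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            tissue_fraction(np.zeros((5, 5), dtype=bool),
                            np.zeros((5, 5), dtype=bool))

    def test_phantom_hole_fraction_recovered_exactly_prenoise(
            self, small_phantom):
        image, truth, _ = small_phantom
        from zonemetrics import background_mask, rgb_to_hsv

        bg = background_mask(rgb_to_hsv(image))
        pct, _ = tissue_fraction(truth.zone_masks["LZ"], bg)
        assert pct == pytest.approx(truth.tissue_pct("LZ"), abs=1e-9)


class TestLzJzBorder:
    def test_abutting_rectangles_match_cross_pair_oracle(self):
        lz = np.zeros((70, 40), dtype=bool)
        jz = np.zeros((70, 40), dtype=bool)
        lz[10:60, 10:20] = True
        jz[10:60, 20:30] = True
        path = lz_jz_border(lz, jz)
        assert abs(path.length - cross_pair_count(lz, jz)) <= 1.0
        assert cross_pair_count(lz, jz) == 50

    def test_disc_in_annulus_circumference(self):
        h = w = 256
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        r = np.hypot(jj + 0.5 - 128, ii + 0.5 - 128)
        lz = r < 100
        jz = (r >= 100) & (r < 120)
        path = lz_jz_border(lz, jz)
        assert path.closed
        assert path.length == pytest.approx(2 * np.pi * 100, rel=0.02)

    def test_distant_masks_give_empty_border(self):
        lz = np.zeros((30, 30), dtype=bool)
        jz = np.zeros((30, 30), dtype=bool)
        lz[5:10, 5:10] = True
        jz[22:27, 22:27] = True
        with pytest.warns(UserWarning):
            path = lz_jz_border(lz, jz)
        assert path.length == 0.0 and path.is_empty

    def test_symmetry_on_random_wavy_splits(self, rng):
        """length(LZ, JZ) == length(JZ, LZ) within one pixel."""
        for _ in range(5):
            h, w = 60, 80
            split = 25 + np.cumsum(rng.integers(-1, 2, w))
            split = np.clip(split, 10, 50)
            cols = np.arange(w)
            rows = np.arange(h)[:, None]
            lz = rows < split[None, :]
            jz = ~lz
            a = lz_jz_border(lz, jz).length
            b = lz_jz_border(jz, lz).length
            assert abs(a - b) <= 1.0

    def test_pixel_size_scales_length(self):
        lz = np.zeros((20, 20), dtype=bool)
        jz = np.zeros((20, 20), dtype=bool)
        lz[5:15, 5:10] = True
        jz[5:15, 10:15] = True
        assert lz_jz_border(lz, jz, pixel_size=3.0).length == pytest.approx(
            3.0 * lz_jz_border(lz, jz).length)


class TestTortuosity:
    def test_straight_path_is_one(self):
        lz = np.zeros((20, 120), dtype=bool)
        jz = np.zeros((20, 120), dtype=bool)
        lz[:10, 10:110] = True
        jz[10:, 10:110] = True
        path = lz_jz_border(lz, jz)
        assert border_tortuosity(path) == pytest.approx(1.0, abs=0.02)

    def test_semicircular_arc_is_half_pi(self):
        r = 100.0
        theta = np.linspace(0, np.pi, 2000)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        path = BorderPath(points=pts, closed=False, length=length,
                          pieces=[(pts, False)])
        assert border_tortuosity(path) == pytest.approx(np.pi / 2, rel=0.02)

    def test_closed_circle_is_one(self):
        h = w = 256
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        r = np.hypot(jj + 0.5 - 128, ii + 0.5 - 128)
        lz = r < 90
        jz = (r >= 90) & (r < 110)
        path = lz_jz_border(lz, jz)
        assert path.closed
        tort = border_tortuosity(path, enclosed_area=polygon_area(path.points))
        assert tort == pytest.approx(1.0, rel=0.02)

    def test_error_contracts(self):
        path = BorderPath(points=np.empty((0, 2)), closed=False, length=0.0)
        with pytest.raises(ValueError):
            border_tortuosity(path)
        loop = BorderPath(points=np.asarray([(0, 0), (1, 0), (1, 1)]),
                          closed=True, length=4.0)
        with pytest.raises(ValueError, match="enclosed_area"):
            border_tortuosity(loop)


class TestMeasureAndExclusion:
    @pytest.fixture(scope="class")
    def measured(self, small_phantom):
        image, truth, session = small_phantom
        cfg = RunConfig(seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meas, ctx = measure_section(image, session, cfg,
                                        return_context=True)
        return meas, ctx

    def test_noiseless_phantom_recovery_within_one_percent(
            self, small_phantom, measured):
        _, truth, _ = small_phantom
        meas, _ = measured
        for z in ZONES:
            assert meas.zone_areas()[z] == pytest.approx(
                truth.zone_pixel_areas[z], rel=0.01)
            assert meas.tissue_pcts()[z] == pytest.approx(
                truth.tissue_pct(z), abs=1.0)
        assert meas.border_length == pytest.approx(
            truth.border_arc_length, rel=0.01)
        total_true = sum(truth.zone_pixel_areas.values())
        assert meas.total_area == pytest.approx(total_true, rel=0.01)
        assert meas.tortuosity >= 1.0 - 0.02

    def test_determinism_two_runs_identical(self, small_phantom):
        image, _, session = small_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = measure_section(image, session, RunConfig(seed=7))
            b = measure_section(image, session, RunConfig(seed=7))
        for f in ("total_area", "lz_area", "jz_area", "decidua_area",
                  "border_length", "tortuosity", "lz_tissue_pct"):
            assert getattr(a, f) == getattr(b, f)
        assert a.provenance == b.provenance

    def test_missing_outline_error_names_zone(self, small_phantom):
        image, _, session = small_phantom
        from zonemetrics import SessionSpec

        broken = SessionSpec(
            image_id=session.image_id,
            cluster_index="auto",
            zone_outlines={z: session.zone_outlines[z] for z in ("LZ", "JZ")},
        )
        with pytest.raises(ValueError, match="decidua"):
            measure_section(image, broken, RunConfig(seed=7))

    def test_exclusion_conserves_area_exactly(self, measured):
        meas, ctx = measured
        # a disc overlapping the LZ
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        disc = np.stack([128 + 20 * np.cos(theta),
                         128 + 20 * np.sin(theta)], axis=1)
        excl_mask = outline_to_mask(ZoneOutline("exclusion", disc), (256, 256))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, after = apply_exclusion(ctx, [disc])
        for zone, field in (("LZ", "lz_area"), ("JZ", "jz_area"),
                            ("decidua", "decidua_area")):
            overlap = int(np.count_nonzero(ctx.zone_masks[zone] & excl_mask))
            before = getattr(meas, field)
            assert getattr(after, field) == before - overlap
        union = np.zeros_like(excl_mask)
        for z in ZONES:
            union |= ctx.zone_masks[z]
        assert after.excluded_area == int(np.count_nonzero(union & excl_mask))

    def test_disjoint_exclusion_is_a_noop(self, measured):
        meas, ctx = measured
        square = [(2, 2), (8, 2), (8, 8), (2, 8)]  # corner: outside section
        _, after = apply_exclusion(ctx, [np.asarray(square, dtype=float)])
        assert after.lz_area == meas.lz_area
        assert after.border_length == meas.border_length
        assert after.excluded_area == 0.0

    def test_exclusion_crossing_border_matches_recount(self, measured):
        """Border length after exclusion equals a direct recomputation
        on the truncated masks."""
        meas, ctx = measured
        rect = np.asarray([(120, 0), (136, 0), (136, 256), (120, 256)],
                          dtype=float)
        excl = outline_to_mask(ZoneOutline("exclusion", rect), (256, 256))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, after = apply_exclusion(ctx, [rect])
        direct = lz_jz_border(ctx.zone_masks["LZ"] & ~excl,
                              ctx.zone_masks["JZ"] & ~excl,
                              adjacency_tol=ctx.adjacency_tol,
                              resample_step=ctx.resample_step)
        assert after.border_length == pytest.approx(direct.length)
        assert after.border_length < meas.border_length

    def test_resolution_consistency(self):
        """Doubling phantom resolution changes normalized areas < 1 %
        and border length < 2 %."""
        results = {}
        for scale in (1, 2):
            spec = PhantomSpec(
                size=(256 * scale, 256 * scale), r_lz0=50.0 * scale,
                wave_amplitude=5.0 * scale, r_jz_outer=80.0 * scale,
                r_dec_outer=110.0 * scale, noise_sigma=0.0, seed=3,
                hole_fraction={z: 0.0 for z in ZONES})
            image, truth = generate_phantom(spec)
            session = make_session_from_truth(truth)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                meas = measure_section(image, session, RunConfig(seed=3))
            results[scale] = meas
        a, b = results[1], results[2]
        for f in ("lz_area", "jz_area", "decidua_area"):
            assert getattr(b, f) / 4.0 == pytest.approx(getattr(a, f),
                                                        rel=0.01)
        assert b.border_length / 2.0 == pytest.approx(a.border_length,
                                                      rel=0.02)
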