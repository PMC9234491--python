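# Methods

This note documents the models, algorithms and numerical choices behind
`zonemetrics`, the defaults and why they were chosen, and what the
synthetic validation can and cannot show about real tissue.

## The measurement problem

An H&E-stained placental cross-section contains three concentric
layers with distinct staining: the eosin-pink labyrinth zone (LZ), the
purple junctional zone (JZ) and the darker maternal decidua, on a
near-white slide background with tissue-free holes (vessels, lacunae,
processing artifacts). The pipeline turns one RGB photomicrograph plus
a *session file* — the record of what an operator would otherwise be
prompted for interactively (reference-cluster choice, one outline
polygon per zone, optional exclusion polygons) — into per-section
quantities: total and per-zone areas, per-zone tissue percentages,
LZ–JZ border length, and border tortuosity.

## Color model and segmentation

**Intensity normalization.** Stain intensity and contrast vary between
slides. Before clustering, each RGB channel is percentile-stretched:
values at/below the `norm_low_pct` (default 0.01) quantile map to 0,
at/above `norm_high_pct` (default 0.99) to 1, linear between. This is a
robust, deterministic normalization; the stretch feeds only the CMYK
clustering stage. Hue-based steps (peak segmentation, zone-color
assignment, background detection) operate on the *raw* image, because
their reference colors are defined on raw stain colors and a
per-channel affine stretch distorts hue. A constant channel is passed
through unchanged with a warning.

**CMYK clustering.** The naive ink-subtraction CMYK is used
(K = 1 − max(R,G,B); C = (1−R−K)/(1−K), analogously M, Y; C=M=Y=0 at
K=1): no ICC profiles, since only the relative geometry of colors
matters for clustering. Pixels are partitioned in 4-D CMYK space by
k-means with k = 8 (`k_clusters`), seeded k-means++ initialization and
Lloyd iterations (max 100), via scikit-learn. On images above 200 000
pixels the centroids are fit on a seeded random subsample of that size
and all pixels are assigned to their nearest centroid; this keeps
runtime linear and is bit-reproducible for a fixed seed. Empty clusters
are permitted and reported (an image with fewer distinct colors than k
cannot fill all clusters).

**Reference-cluster choice.** The original interactive workflow asks
the operator for the cluster that is "brightest in all placental
zones". Manual mode reproduces that contract (the session supplies the
index). Auto mode returns the cluster with the highest mean brightness
(mean V, computable in CMYK as 1 − K) among clusters holding at least
`ref_min_frac` (default 1 %) of the pixels, after excluding clusters
whose pixels are mostly (≥ 50 %) background-like — the unstained
background is the brightest thing on any slide but is not a placental
zone, so a bare argmax would always pick it.

**HSV peak segmentation.** Within the reference cluster, a circular
hue histogram (default 64 bins) is built over saturated pixels
(S ≥ `s_floor` = 0.05), weighted by saturation. Local maxima with
positive mass, ranked by height and thinned to a circular separation of
≥ `peak_min_separation` (default 2) bins, become up to `n_peaks`
(default 8) segment seeds; each reference-cluster pixel joins the
circularly nearest peak hue. Hue is circular throughout (0 ≡ 1);
zero-saturation pixels have undefined hue, stored as 0 and flagged, and
hue terms are dropped for them in color distances. If the reference
cluster contains no saturated pixel at all, a single segment is
returned with a warning.

**Zone assignment.** Each zone has a reference stain color in HSV
(defaults: LZ pink (0.97, 0.45, 0.85), JZ purple (0.78, 0.55, 0.55),
decidua dark violet (0.72, 0.50, 0.35) — package defaults chosen to
represent typical H&E appearance, overridable per config or session).
A zone maps to the segment minimizing the weighted circular-HSV
distance d = √(w_h Δh² + w_s Δs² + w_v Δv²) with weights (2, 1, 1):
hue separates stains most reliably, so it is weighted up. Ties go to
the lowest segment index with a warning; two zones may share a segment
(warning), in which case the segment is *owned* by the nearest zone.

## From outlines and segments to zone masks

Rasters are row-major, origin top-left; polygon vertices are (x, y)
in pixel units with the center of pixel (i, j) at (j + 0.5, i + 0.5).
A pixel belongs to a polygon iff its center is inside under the
even-odd rule. Rasterization is an in-package scanline crossing count:
the crossing comparison is division-free and falls back to exact
rational arithmetic for centers within float noise of an edge, so the
rule is honored exactly (a property the test suite checks against
independent brute-force oracles). Self-intersecting input polygons are
repaired with shapely before rasterization.

A zone's outline is a *candidacy* region (it may be drawn generously;
outlines of adjacent zones may overlap). The final per-pixel zone label
combines three rules, in order:

1. a tissue pixel whose HSV segment is owned by a zone joins that zone
   if the zone's outline contains the pixel;
2. any other tissue pixel inside at least one outline joins the
   candidate zone with the nearest reference stain color;
3. background pixels *not* connected to the image border (holes,
   lumens, tissue-free space inside the section) join the zone of the
   geometrically nearest zone-classified tissue pixel (Euclidean
   feature transform) among their candidates; border-connected
   background is exterior and belongs to no zone.

Rule 3 is deliberate: zone areas are defined by the outlined region
including its tissue-free space — that is what makes the "percentage
of the zone containing tissue" a meaningful, separate quantity. A
`mask_rule = "outline"` config switch disables rules 1–3 and uses the
outline interiors directly (overlaps resolved in LZ > JZ > decidua
order) for purely geometric studies.

Background/tissue discrimination: a pixel is background iff V ≥
`bg_v_min` (0.92) and S ≤ `bg_s_max` (0.12); these defaults separate
unstained slide from even weakly stained tissue and are config keys.

**Areas** are pixel counts × pixel_size². `pixel_size` defaults to 1.0
(results in px/px²) because magnification alone does not fix a µm/px
calibration; supply one for physical units.

## Border length and tortuosity

LZ boundary pixels (4-adjacent to a non-LZ pixel or the image edge)
lying within `adjacency_tol` (default √2 px) of a JZ boundary pixel
form the shared border; symmetrically for the JZ side. Each 8-connected
component is ordered by marching (start at a degree-1 endpoint when one
exists, greedy walk preferring lateral moves, deterministic
tie-breaks). Length is the polyline through every 5th traced pixel
(`border_resample_step`), summed over components, averaged between the
LZ-side and JZ-side traces, and scaled by pixel_size.

Two numerical choices matter here. A raw lateral/diagonal chain sum
overestimates the length of a smooth digitized curve by ≈ 5 % (the
classic Freeman chain-code bias); resampling every 5 pixels removes
this while leaving straight axis-aligned borders exact. Averaging the
two one-sided traces makes the measure symmetric in its arguments by
construction and cancels the half-pixel inside/outside offset of the
two pixel fronts. On a digitized circle of radius 100 px the combined
estimator is accurate to ≈ 0.2 %.

Tortuosity of an open border is length / endpoint chord; of a closed
border, length / 2√(π·A) with A the shoelace area enclosed by the
traced loop — the perimeter of the equal-area circle, so a circle
scores 1 regardless of radius. Both are ≥ 1 up to discretization
(the suite allows 2 % slack). Undefined cases (empty border, zero
chord, missing area) raise or yield NaN rather than a silent 0.

**Exclusions** (operator-marked regions such as chorionic plate or
yolk-sac remnants) are rasterized, unioned, removed from every zone
mask and the total-area mask, and all quantities are recomputed;
per-zone area changes equal the integer pixel overlaps exactly, and the
removed area is recorded. Total area is the union of the final zone
masks minus exclusions.

## Aggregation

Sections (typically four per placenta) are collapsed into one row per
placenta: extensive quantities (areas, border length, excluded area)
are summed with `math.fsum` (exact, hence order-independent); intensive
quantities (tissue percentages, tortuosity) are averaged with equal
weights — summing percentages across sections would not be meaningful.
A count other than four sections triggers a warning, not an error.
Area-like columns are min–max rescaled across placentas
((x − min)/(max − min); a constant column maps to 0.5 with a warning).
The output table carries dam id, treatment, fetal sex and fetal mass
(missing mass is an explicit NaN) so that mixed models with a dam
random effect and fetal-mass covariate can be fit directly in external
statistics software.

## The phantom model

`generate_phantom` renders an annular section: an LZ disc bounded by
the polar curve r(θ) = r₀ + A·sin(kθ), a JZ annulus to `r_jz_outer`, a
decidua rim to `r_dec_outer`, zones filled with their reference stain
colors on a near-white background (RGB 0.97). Defaults: 512² raster,
r₀ = 100 px, A = 10 px, k = 8, r_jz = 160, r_dec = 220, per-zone hole
fraction 0.05, hole radii 3–8 px, noise σ = 0.02 — a mid-size section
with a visibly wavy border and moderate scan noise. Circular,
non-overlapping holes are placed by seeded rejection sampling entirely
inside their zone until the realized pixel fraction is within 0.5
percentage points of the target (the final disc is shrunk to land on
the target, never below the configured minimum radius; an impossible
combination raises). I.i.d. Gaussian RGB noise is added last and
clipped; ground truth (zone masks, hole raster, realized fractions,
dense border polyline) is recorded pre-noise. The analytic border
length is ∫√(r² + r'²) dθ by trapezoidal integration on 10⁵ points —
exact for A = 0 and convergent to < 0.1 % under grid doubling
otherwise. Everything is deterministic per seed.

`make_session_from_truth` stands in for a human tracing: each zone's
outline is the simplified outer contour of its mask dilated by 2 px,
so outlines generously contain their zones, and annular zones get a
filled outer contour whose interior the segmentation rules resolve.
Cluster choice is left on "auto".

**What passing phantom tests shows — and does not.** The phantom
validates the measurement chain: rasterization, classification by
color, hole accounting, border tracing and the length/tortuosity
estimators, under known geometry and noise. It does not emulate
texture, nuclei, stain gradients, scanner shading, folds or debris;
zone colors are flat and well separated, so segmentation accuracy on
phantoms is an upper bound on real-tissue accuracy. In particular,
because phantom zones are single flat colors, the brightest tissue
CMYK cluster spans only one zone's color; the mask rules (2)–(3) above
carry the other zones, which is exactly the fallback a real section
with weak cluster overlap would exercise.

## Problem sizes and reproducibility

The test suite and the acceptance script validate at 512² (single-
phantom recovery, 30-phantom tissue-fraction sweep, 10-seed noisy-
segmentation sweep) and 1024² (wavy border), with smaller 256²
phantoms for unit and batch tests — sizes chosen to exercise the full
pipeline at realistic section scale while keeping a full validation
run in the low minutes on one CPU. All randomness (k-means
initialization and subsampling, phantom holes and noise) flows from
explicit integer seeds; reruns with equal inputs, config and seed are
bit-identical, and every output row embeds the config and session
hashes plus the seed.

## Known limitations

- The CMYK conversion and percentile normalization are documented
  substitutes for an unspecified original workflow; they are not claims
  about any particular MATLAB internals.
- Auto reference-cluster selection assumes background is bright and
  unsaturated; heavily stained or dark-field images need manual mode.
- Border tracing assumes a locally 1-pixel-wide interface; pathological
  masks (checkerboards, thick overlap bands) are traced deterministically
  but the length of such interfaces is not well defined.
- Tortuosity of a border broken into many components uses the longest
  piece's chord (open case); heavily fragmented borders are better
  interpreted via total length alone.
- Tissue percentages use a global background threshold; faint tissue
  near the threshold (e.g. edema) may count as background.
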