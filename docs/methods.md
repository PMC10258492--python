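# Methods

## The measurement problem

Muscle growth after hatch is hypertrophic: fiber number is fixed early, so
development and treatment effects show up as changes in fiber size and,
reciprocally, in the number of fiber profiles per unit of section area.
The quantities of record are the per-fiber **lesser diameter** and
**cross-sectional area** of transverse profiles in stained sections, and
their per-section aggregates. Broiler pectoral muscle is a harder target
than the rodent muscle most published pipelines were tuned on — fiber sizes
are highly variable within one field — which is why every stage here is
scored against ground truth rather than assumed.

## Geometry

**Mask → ROI conversion.** A fiber arrives as one label in an integer mask.
Its outer boundary is traced along the pixel "cracks": pixels are unit
squares with corners on the half-integer grid, and directed boundary edges
are chained into a single closed ring (at corners where diagonally touching
pixels pinch the boundary, the walk takes the sharpest left turn, which
keeps an 8-connected region on one contour). The shoelace area of this ring
equals the pixel count exactly — a 2×2 block yields a square of area 4 —
which pins the polygon convention unambiguously. Interior holes are filled
before tracing and measurement: a myofiber cross-section is simply
connected, so unstained interior spots are artifacts.

**Lesser diameter = minimum Feret diameter.** The minimum width over all
caliper orientations. For a convex polygon the minimum is attained with one
jaw flush against a hull edge, so it suffices to scan hull edges and take
the farthest-vertex distance to each edge's supporting line (rotating
calipers); the implementation is validated against an exhaustive
projection-width sweep at 0.01° steps to within 0.1% relative. Degenerate
(collinear) regions return width 0 with a warning rather than an error.
Digitization adds roughly half a pixel per side: a digitized disk of radius
r measures 2r within 2 px, and at the default 6.6 px/µm calibration the
bias is ≈ 0.1 µm on a 23 µm fiber.

**Area.** Hole-filled pixel count divided by (px/µm)². No sub-pixel
boundary correction is attempted; at the fiber sizes of interest the
quantization error is well below biological variability.

**Calibration.** The acquisition setup this models states a "µm to pixel
ratio of 6.6", which is dimensionally ambiguous; it is interpreted as 6.6
pixels per µm (≈0.15 µm/px), since 6.6 µm/px would render a 22 µm fiber
about 3 px wide and unmeasurable. Calibration is always an explicit
parameter; 6.6 px/µm is only the documented default.

## Segmentation

The deep-learning detector used in the original workflow is neither bundled
nor re-trained: the hand-off contract is the label mask, and any external
segmenter's mask is ingested as-is (`--backend mask`). The in-repo
classical backend makes the pipeline self-sufficient:

1. stain score `s = (G − R + 255)/510` per pixel — 1 for pure green
   (fiber), 0 for pure red (connective tissue), 0.5 for gray — optionally
   Gaussian-smoothed (`smoothing_sigma_um`, default 1 µm);
2. foreground by Otsu's threshold on the score (parameter-free; the
   original workflow names no threshold);
3. Euclidean distance transform of the foreground; markers at distance
   maxima surviving h-maxima suppression at depth `h_maxima_um`
   (default 2 µm). Fiber profiles are near-convex, so their distance
   function is close to concave and usually yields exactly one marker;
   merged neighbors get split by the watershed;
4. marker-controlled watershed on the negated distance map, restricted to
   the foreground.

Label QC (`filter_labels`, common to both backends) removes debris below
`min_area_um2` (default 50 µm², about an 8 µm equivalent diameter — below
the smallest populated bin of real diameter distributions) and, by default,
fibers touching the image border, whose truncated profiles bias the lesser
diameter downward. Whether the original analysis excluded edge fibers or
imposed a minimum size is not stated; both choices are explicit parameters
here. Filtering is idempotent and renumbers survivors 1..K in original
order.

Segmentation quality is scored by optimal one-to-one matching (Hungarian
assignment on the IoU matrix) against ground truth; the pipeline's own bar
is ≥90% of border-excluded true fibers matched at IoU ≥ 0.5 — on clean
synthetic sections it typically matches 98–99%.

## Synthetic sections

The generator exists because the original image set is not public: it
supplies inputs with known answers, at the study's reported morphology.

- **Territories:** Voronoi cells of a jittered grid (jitter 0.8 of half the
  spacing by default; pure Poisson sampling produces pathological slivers).
  Grid spacing is 1.55 × (target mean diameter + border width), sized so
  cells can accommodate the upper quantiles of the size distribution.
- **Sizes:** target lesser diameters are drawn from a Gaussian with the
  requested mean and CV, truncated at zero by redrawing. Real diameter
  histograms are near-symmetric with the modal 5 µm bin at the mean
  ([20, 25) µm for 14-day-old broiler pectoral muscle); a lognormal at
  CV 32% was tried first and rejected because its skew splits the mass
  evenly between [15, 20) and [20, 25), contradicting that shape.
- **Realization:** each cell is eroded inward until its minimum caliper
  width equals its target (draws are rank-matched to cell widths, largest
  to widest, so truncation by too-small cells is negligible — about 1% of
  fibers). Erosion of a convex polygon is the unlimited-mitre inner offset;
  the offset achieving a given width is found by bisection, because sharp
  vertices lose more than twice the offset of width and a closed-form rule
  under-sizes fibers by 3–4%.
- **Borders:** every cell is additionally eroded by half the border width
  (default 2 µm, an endomysium scale), guaranteeing ≥ border width of
  background between any two fibers; no two labels are ever 8-adjacent.
- **Edges:** fibers crossing the frame are cut flush at the image edge and
  kept, so border-exclusion filtering has real work to do.
- **Rendering:** fiber pixels green-dominant (70, 180, 90), background
  red-dominant (200, 75, 70), with ±5% uniform multiplicative noise. All
  randomness flows from one integer seed; identical parameters give
  bit-identical outputs.

What the generator does **not** emulate: staining gradients and uneven
illumination, out-of-focus and stitching artifacts, non-convex or split
fibers, nuclei, fat, vessels, and pathology (wooden breast, white
striping). Passing the synthetic bars therefore demonstrates the geometry,
bookkeeping, and classical-segmentation logic — not robustness to difficult
real-world staining, for which an external (e.g. deep-learning) mask
backend is the intended route.

Default problem sizes: unit tests run one shared ~110-fiber section
(800×800 px at 2 px/µm); parameter-recovery and matching bars run one
~1060-fiber section (2500×2500 px at 2 px/µm). 2 px/µm keeps fibers ~45 px
across — far above the resolution where quantization would matter — while
sections generate and segment in seconds.

## Aggregates and statistics

- SEM uses the sample SD (n−1); CV = sample SD / mean × 100 (undefined
  below n = 2 or at zero mean — validation errors, except in section
  summaries where missing aggregates are NaN).
- Diameter histograms use left-closed bins [0, 5), [5, 10), … (5 µm
  default).
- Fiber density divides the fiber count by the **stained-tissue** area:
  pixels whose stain score exceeds 0.05 or that belong to a fiber, closed
  with a 5 µm-radius disk to bridge endomysial gaps. Normalizing to tissue
  rather than the full frame matches the stated intent of per-section
  normalization, but since the alternative cannot be ruled out, the
  full-image-area density is reported alongside
  (`fibers_per_mm2_image`).
- **Accuracy rate** `(1 − |test − reference|/reference) × 100` is
  asymmetric — the denominator is always the reference (manual) value — so
  reports label direction explicitly. It equals 100 iff the values are
  equal and decreases linearly in their absolute difference.
- **Productivity** counts data sets per hour; a fiber measured for both
  diameter and area contributes two data sets, a diameter-only (manual)
  measurement one. This is the only counting rule consistent with the
  published throughput figures on both the automated and the manual side.
- **Method comparison** pools fibers across sections via exact
  (n, mean, SD) pooling, so only the pooled multiset matters, not how
  fibers were partitioned into images.
- **Group comparison** runs one-way ANOVA across the two groups followed by
  a pooled-variance Student's t test per metric (for two groups the two are
  the same test: F = t²). Diameter and area are tested at the **fiber**
  level: reported SEMs of ±0.03–0.06 µm on ~20,000 fibers are only
  attainable with fiber-level n. This treats fibers within an image as
  independent — pseudoreplication that anticonservatively shrinks p-values
  when birds or images differ systematically; a mixed model with bird/image
  nesting would be the stricter choice and is deliberately out of scope.
  Density is an image-level quantity and is tested across images. No
  multiple-testing correction is applied across the three metrics.

## Numerical and edge-case conventions

- Non-8-bit images are linearly min–max scaled per channel to 8-bit at
  read time; constant channels map to zero. Calibration never alters
  stored pixels.
- A uniform or foreground-free image segments to an empty mask with a
  logged warning, not an exception; empty masks flow through measurement as
  zero-fiber summaries with NaN means.
- Labels need not be contiguous integers, but each must form one connected
  component at the configured connectivity (8 by default); violations name
  the offending label.
- Exported tables use UTF-8, '.' decimal separator, 6-decimal floats;
  CSV is canonical and XLSX (same columns) mirrors spreadsheet-centric
  downstream workflows.

## Known limitations

- The classical backend presumes the green/red stain contrast; it is not a
  general fiber segmenter and will fail on other stains (use the mask
  backend there).
- Lesser diameter is computed on the convex hull; for strongly concave
  profiles (rare in healthy transverse sections) the hull width can exceed
  any intuitive "width" of the shape.
- Wall-clock productivity of a real analysis depends on hardware and
  operator; analysis hours enter only as user-supplied inputs.
- The synthetic generator's fibers are convex by construction; segmentation
  scores on it are an upper bound on real-data performance.
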