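# Methods

This note documents the measurement model, its conventions and defaults, the
synthetic benchmark, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Scene model and segmentation

An input photograph is assumed to follow the field imaging protocol: a
washed, excavated root crown photographed against a dark, diffusely
reflecting background that also contains one light-colored circular scale
marker of known physical diameter, and optionally a rectangular
identification tag placed above the root. Color images are reduced to
luminance (0.299 R + 0.587 G + 0.114 B); 8- and 16-bit integer data are
rescaled to [0, 1].

Segmentation is a single **global threshold** — foreground iff intensity
> *t* — followed by one binary opening with the 3×3 cross element to remove
speckle. A global threshold matches the protocol's controlled dark
background and keeps calibration a one-parameter visual choice
(`dirt-calibrate` renders the mask at several candidate thresholds). The
cross-opening clips the four corner pixels of perfectly sharp convex
corners; this is irrelevant at the scale of real silhouettes and accepted as
the price of speckle removal.

Components (8-connectivity throughout; 0-based half-open bounding boxes;
row increases downward, so *depth* = row) are classified in order:

1. **marker** — the component with the highest isoperimetric quotient
   4πA/P² among those with quotient ≥ `c_min` (default 0.7) and area ≥
   `a_min` (default 200 px). Perimeter is the count of foreground pixels
   4-adjacent to background. The quotient is parameter-light and needs no
   Hough transform; note that compact solid shapes (squares score ≈ 0.84)
   can pass the gate, so markers should be the only bright compact object
   in the scene, as the protocol prescribes.
2. **tag** — the largest remaining component with bounding-box fill ratio
   ≥ 0.75 whose centroid lies above the top edge of the largest remaining
   component. Tags are localized only (for external barcode/QR decoding via
   `crop_tag`); no decoding is attempted.
3. **root** — the largest unclaimed component; everything else is residual.

Calibration uses the marker's equivalent diameter d = 2√(A/π), which is
robust to small boundary raggedness; rasterized discs with radii 20–100 px
recover their diameter to well under 2 %. When no marker is found the image
is *not* failed: traits are reported in pixel units with a `px` unit flag.

## Skeleton, collar and root-tip paths

The root mask's exact Euclidean distance transform (pixel-center metric: a
single foreground pixel has distance 1) supplies a medial radius for every
pixel of the topology-preserving thinning (Zhang-style skeletonization).
The skeleton is abstracted into a graph whose nodes are tips (one skeleton
neighbor) and junction clusters (8-adjacent pixels with ≥ 3 neighbors) and
whose edges are maximal degree-2 pixel chains with length Σ steps (1 or √2).

**Spur pruning** iteratively removes tip-terminated edges shorter than
max(`min_spur_len`, 1.5 × medial radius at their junction), dissolving
junctions that degrade to degree 2, to a fixpoint; the last edge of a
component is never removed. The radius-proportional term removes the corner
branches that thinning produces at blunt stroke ends without touching true
laterals; `min_spur_len` defaults to 10 px and is recorded in the manifest.

The **collar** is the topmost skeleton tip (ties broken by proximity to the
root centroid column) — the point where the stem enters the crown. A
**root-tip path (RTP)** is the minimum-arclength graph path from the collar
to each tip. Minimum arclength was chosen over steepest-descent tracing
because it is unambiguous on graphs with cycles and reproduces drawn stroke
geometry on the synthetic benchmark. Each path carries per-point depth
(row), medial radius and tangent angle: the absolute angle from horizontal,
in [0, 90] (steeper = larger), of the secant over a centered window of
`tangent_window` = 9 polyline points. The window trades pixel-quantization
noise (a 9-point secant resolves ~4°) against curvature smearing; it is
config-exposed.

## Trait conventions

- Depth fractions are measured inside the root bounding box: row *i* of an
  *H*-row box has depth fraction *i*/(*H*−1).
- **Widths** are horizontal *extents* (rightmost − leftmost + 1 per row),
  not pixel counts — a C-shaped crown is as wide as its span. Pixel counts
  are kept separately and feed `AVG_DENSITY`.
- D*x* is the depth fraction at which the cumulative row-width sum first
  reaches *x* % of its total; DS*x* is the central-difference slope of the
  normalized cumulative curve there.
- **Diameters** are 2 × medial radius. `DIA_STM` is the median over
  central-path points (the central path is the longest RTP) in the top
  `f_stem` = 0.05 of root depth, widened to the top 10 rows when the band is
  empty; `DIA_STM_SIMPLE` is the median row extent over the same band.
- **Top/bottom angles** (`ANG_TOP`, `ANG_BTM`): per side, a total
  least-squares line (principal direction of the centered point cloud) is
  fitted to the outermost boundary pixel per row within the top
  `f_top` = 0.3 (resp. bottom `f_btm` = 0.3) depth band; the trait is the
  mean over the two sides, each side requiring ≥ 5 boundary pixels.
- **Monocot angle statistics**: STA samples the tangent where each path
  first reaches depth fractions {0.25, 0.5, 0.75, 0.9}; RTA samples the
  tangent at 90 % of each path's own arclength. Dominant angles are the
  centers of the two most populated 10°-wide histogram bins (ties go to the
  steeper bin); `_I`/`_II` side statistics split paths by the side of the
  collar column at the sample point, the larger population being side I.
- **Dicot branches** leaving the taproot (= central path) are classified by
  junction depth fraction z: adventitious z ≤ 0.05, basal 0.05 < z ≤ 0.15,
  lateral otherwise. The **emergence angle** is the angle between the
  taproot tangent at the junction and the branch's initial secant. Because
  the medial axis bends toward its parent within roughly one medial radius
  of a junction, the branch secant starts beyond a 1.5 × junction-radius
  exclusion zone (falling back to the whole first edge for short branches);
  without the exclusion the measured angle is biased steep by 15–20° at
  realistic taproot widths.
- **Excised samples**: every component with area ≥ `a_root` (default
  200 px) is a segment (smaller components are debris); each segment is
  skeletonized independently for lengths, diameters, tip counts and the
  branching frequency (tips − 2·segments, floored at 0, per unit length).

All length/area traits divide by the calibrated pixels-per-mm (or its
square), so mm/px homogeneity is exact by construction; all angle traits are
defined through absolute values and are mirror-invariant.

## Synthetic benchmark

The generator renders protocol-compliant scenes whose ground truth is
analytic, not measured: binary-valued constant-width strokes (intensity
0.9) on a noisy dark background (level 0.08, Gaussian σ default 0.03,
clipped), a rasterized marker disc (default 60 px / 12 mm → 5 px/mm) and a
tag rectangle, with pairwise-disjoint regions enforced. A stroke of width
*w* covers pixel centers strictly within *w*/2 of its centerline, so even
widths measure exactly *w* under the 2×-EDT diameter convention; generator
defaults therefore use even widths.

- `monocot_fan` — a vertical stem (width = the `DIA_STM` ground truth) from
  the collar to a branch point at 10 % depth, then straight strokes fanning
  to a common depth (450 px by default). Ground-truth widths come from the
  per-row extent formula of the stroke envelope; the bottom angle from the
  outermost stroke angles; the top angle from the same total-least-squares
  fit applied to the *analytic* boundary polyline (stem edge + outermost
  stroke edge). The RTP-count ground truth is only asserted when adjacent
  strokes provably separate well before their tips.
- `dicot_taproot` — a vertical taproot with straight laterals at known
  depths and angles, alternating sides.
- `excised_segments` — disjoint horizontal bars; segment skeleton length
  ground truth is L − w (medial axis of a blunt bar), with tolerances
  covering end effects. Default segments are larger than the tag so that
  the size-based scene classification stays unambiguous.

The validation suite draws 50 fans with per-item seeds (seed + i): opening
angles 20–80° (each side uniform 10–40°), stem widths 8–40 px (even),
5–25 strokes, stroke width 6–8 px, noise σ uniform in [0.01, 0.05]. On this
suite the five field-validated traits (stem diameter, median and maximum
width, top and bottom angle) are required to track ground truth with
R² ≥ 0.9 per trait and per-image errors within ±3° (angles), ±10 % (stem
diameter) and ±2 px (widths); the acceptance script reports the measured
R² values.

What the generator does **not** emulate — and hence what passing tests do
not establish for field photographs: soil residue and specular highlights,
uneven illumination, perspective distortion, root overlap/occlusion beyond
incidental stroke merging, blur, and texture within the root. The benchmark
validates the measurement geometry, not photographic robustness; the
threshold calibration tool exists precisely because real backgrounds vary.

## Batch behavior and determinism

The pipeline contains no randomness: identical inputs give identical
records. Batch output rows follow sorted input file names regardless of
worker count or completion order, so trait CSVs are byte-identical for any
parallelism level. Every stage failure is contained per image and recorded
in the manifest as `failed:<stage>`; blank scenes give `no-root` and
marker-less scenes `no-marker(px-units)`. Values are serialized with 10
significant digits, which round-trips doubles well beyond the 6-digit
contract.

## Known limitations

- A single global threshold cannot rescue images with background gradients;
  adaptive thresholding is deliberately out of scope.
- Side statistics attribute each sample to left/right of the collar column;
  crowns whose stem is strongly tilted may mix sides near the midline.
- Tags more compact than ~4:3 can score above the marker circularity gate;
  the protocol's elongated label placement avoids this.
- Trait definitions in the monocot and dicot families are self-consistent
  reconstructions of the published output vocabulary, validated against the
  synthetic benchmark rather than against the original implementation.
- RSML is written, not read; ingesting manual RSML annotations (e.g. from
  interactive tracing tools) is future work.
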