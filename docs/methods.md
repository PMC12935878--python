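# Methods

## Imaging model and calibration

The pipeline assumes the acquisition protocol common in desk-top panicle
phenotyping: one detached panicle photographed against a uniform dark
background, with a red circular reference disk of known physical
diameter (default 30 mm) lying flat in the scene. Calibration searches
connected components of a red-dominance mask (R ≥ 1.5 G, R ≥ 1.5 B,
R ≥ 80), scores each candidate by circularity (4πA/P²) times the red
fraction inside its fitted circle, and accepts the best candidate that
clears both thresholds (circularity ≥ 0.75, red fraction ≥ 0.6). The
disk radius is the equivalent-area radius √(A/π), which is insensitive
to single-pixel boundary noise, and mm/px = diameter / (2 r). Two
near-equal candidates raise an ambiguity error rather than silently
picking one. Lens distortion is not modelled; the scale is assumed
uniform over the scene.

All coordinates are (row, col), 0-based; boxes are half-open
[r0, r1) × [c0, c1).

## Segmentation

Luma (0.299 R + 0.587 G + 0.114 B) → median filter (disk radius 2,
edge-preserving on thin branches; a Gaussian variant is available) →
threshold → morphological closing (disk radius 3) → hole filling →
removal of components under 500 px → blanking of the calibration-disk
region.

The threshold is a three-class Otsu taking the *lower* cut. The scene
has three intensity populations — background, dull rachis, bright
grains — and a plain two-class Otsu drifts into the rachis/grain gap
when the grains are very bright (late maturity stages), severing the
rachis from the mask and with it the skeleton's spine. The lower
multi-Otsu cut separates background from plant regardless of the grain
brightness. Hole filling matters beyond cosmetics: a simply connected
mask yields a cycle-free skeleton, which keeps the longest-path search
linear in practice.

## Panicle length

The largest foreground component is thinned (Zhang–Suen-type
skeletonization). The skeleton graph connects 8-neighbours with weight
1 (orthogonal) or √2 (diagonal); a diagonal edge is omitted when one of
its two orthogonal intermediates is also a skeleton pixel, since the
pair is already connected through it — keeping such edges tiles the
graph with 3-cycles and makes simple-path search combinatorial.
Terminal branches shorter than `spur_px` (default 5) are pruned as
thinning artifacts.

The neck is the lowest (max-row) branching point, preferring among
candidates one whose downward branch is junction-free — i.e. a bare
stalk. This guard matters on real skeletons: a drooping grain lobe can
carry the lowest junction, and taking it would classify the entire
panicle body as "stalk". After pruning the stalk branch, the longest
simple path from the neck is found by iterative depth-first search with
branch-and-bound pruning: a descent is abandoned when the current length
plus the total weight of edges still reachable through unvisited nodes
cannot beat the incumbent. The bound never underestimates the best
completion, so the search is exact; ties break toward the
lexicographically smallest endpoint for determinism.

The reported length is not the raw sum of step weights. Digital
skeletons staircase around the true curve, and the {1, √2} chain length
over-measures smooth curves by up to ~8% at unfavourable orientations (a
classical result in digital geometry). The traced path's vertices are
therefore smoothed with a moving average (window 9, endpoints pinned)
and the polyline length of the smoothed trace is reported; the raw
geodesic sum is kept in the result (`geodesic_px`) for inspection. On
synthetic panicles this reduces the length bias from ≈ +10% to ≈ +2%.

## Grain detection (reference provider)

Grain-level stages consume bounding boxes + confidences through a
provider interface; any external detector can be plugged in via CSV or
JSON. The bundled classical detector selects grain pixels by a
brightness rule (max channel ≥ 115 — grains are brighter than the
rachis), then splits touching grains by watershed seeded at local maxima
of the Gaussian-smoothed brightness and flooded on its negation. Real
grains are glossy — brightest at the core, darker at the rim — so each
visible grain contributes one stable intensity peak and basin even
inside a clump. Seeding and flooding on the same surface is essential:
flooding a distance transform from brightness seeds fragments clumps
into slivers, and distance-transform seeds alone are unstable on
elongated, merged blobs (the split count can even *decrease* as grains
are added).

Confidence is a shape-quality proxy in [0, 1]: solidity × agreement
between region area and fitted-ellipse area. A clean grain scores
~0.95 regardless of elongation; merged clumps and watershed-clipped
fragments fall well below the 0.8 working threshold. (A circularity
based score cannot serve here: a healthy 2.5:1 grain caps near 0.5.)
The 0.8 filter is applied to per-grain measurements — dimensions and
maturity — but **not** to counting, which uses all detections; the
correction regression absorbs the detector's systematic visibility
ratio.

## Grain counting

Two stages. (1) Density classification: occupancy = Σ detection-box
areas / convex-hull area of the panicle mask; class 1 below t1 = 0.50,
class 3 above t2 = 0.65, class 2 between (boundaries assigned upward).
The thresholds are calibrated once against the bundled generator's
density regimes and are not field constants; an injected label (CLI
`--density`) overrides the heuristic, mirroring a deployment where a
trained classifier provides the class. (2) Correction:
Y = a_c X + b_c with the shipped per-class coefficients; output is kept
both as the raw regression value and as an integer (half-away-from-zero,
clamped at 0 — the dense-class intercept is negative, so tiny counts
would otherwise go negative). `fit_correction` refits per class by
ordinary least squares and reports per-class R²; degenerate classes
(constant X, < 3 pairs) are rejected.

## Grain morphometry

For each confident detection the ROI (box padded 4 px) is re-thresholded
with Otsu; the mask is split at its brightness cores (same watershed as
the detector) and the particle owning the ROI centre is kept, holes
filled — "particle filtering" in the sense of removing intruding
neighbour particles and debris below 30 px. The minimum-area enclosing
rectangle of the grain mask is computed exactly (convex hull + rotating
calipers) on pixel-corner polygons — each pixel contributes its four
unit-square corners, so an n-pixel bar measures n, not n−1. Length is
the long side, width the short side, both converted to mm. Grains whose
padded ROI touches the image border are flagged as possibly truncated.

A flat-ROI guard (luma range < 0.1) skips boxes that contain only
background noise rather than segmenting the noise.

## Maturity colour chain

Per grain: mean sRGB over the grain mask → standard sRGB linearization
(v/12.92 below 0.04045, ((v + 0.055)/1.055)^2.4 above) → CIE XYZ via the
sRGB/D65 matrix, scaled so white has Y = 100 → Hunter-type opponent
coordinates a = 175 (X − Y)/Y, b = 70 (Y − Z)/Y → yellowness
YI = (128 L + 100 a + 30 b)/100 → panicle mean → stage bands
milk < 50 ≤ dough < 75 ≤ full maturity ≤ 100 < over-ripe. Bands are
lower-closed/upper-open except that 100 stays in full maturity, because
over-ripe is strictly "greater than 100". "Dough" and "wax-ripe" name
the same stage.

Two lightness conventions are implemented. The default
(`hunter_standard`) is the classical Hunter lightness L = 10 √Y; under
it real grain colours traverse the 50/75/100 bands as maturity
progresses. The alternative (`verbatim`) uses L = 10 Y, under which YI
either saturates far above the bands (XYZ on 0–100) or never reaches
them (XYZ on 0–1); it is retained behind a config switch for audits.
No illuminant adaptation or white balancing is applied; the ASTM E313
yellowness formula is a different quantity and is not implemented.

## Synthetic scene generator

The generator is the package's test bed and defines its study
conditions. A scene (800 × 640 px, 0.3 mm/px via a 50 px-radius disk)
contains: a dark background (level 12, Gaussian sensor noise σ = 2); a
red disk at a fixed corner; a rachis drawn as a quadratic Bézier stroke
with a stalk below the neck; and grains as rotated shaded ellipses
(9 × 3.6 mm mean, 0.5 mm SD, rim 10% darker than core). Panicle length
is sampled per image from 115–190 mm, and the grain total scales with
length at a class-specific linear density, so the count regression sees
genuine spread in X. The ground-truth axis length is the closed-form
Bézier arc length.

Density classes control three things: grains per 100 px of axis
(14 / 22.5 / 33), the placement tube radius around the rachis
(42 / 30 / 20 px, tapering toward the tip), and the hidden fraction
(0.10 / 0.30 / 0.45). Occlusion is modelled by **omission**: hidden
grains are counted in the ground-truth total but never rendered, giving
an exact visible/total ratio with inverse-visibility slopes
1.11 / 1.43 / 1.82 — ordered like the shipped correction slopes — which
is precisely the mechanism the correction regression models. Rendered
grains are placed with a per-class cap on mutual overlap (normalized
centre-distance rejection), so visible grains keep an exposed core; two
basal anchor branches with grains guarantee a skeleton junction at the
neck, and tip grains align with the axis like the terminal spikelet.
Stage palettes (green → yellow-green → yellow → deep golden) are chosen
so the mean YI of a panicle lands mid-band for its generating stage.

What the generator does **not** emulate: perspective and lens
distortion, shadows and specular highlights, awns, overlapping leaves or
field backgrounds, and true 3-D occlusion geometry (hidden grains vanish
rather than peek out). Passing the recovery suite therefore demonstrates
the correctness and internal consistency of the measurement chain under
the stated imaging model, not field-condition robustness.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirror tests) run:

* **Trait recovery**: 150 panicles, 50 per density class, stages
  cycling, single master seed. Scores: panicle-length MAPE; held-out R²
  of corrected counts (regressions refitted on the even-index half,
  scored on the odd-index half, pooled over classes); maturity-stage
  agreement; density-classifier accuracy. Count regressions are fitted
  and applied under the generating density label so the regression
  experiment is not confounded by classifier mistakes; the classifier is
  scored separately.
* **Morphometry recovery**: 200 grains in scattered non-overlapping
  fields (no occlusion), matched to ground truth at IoU ≥ 0.5; mean
  absolute length/width error in px. In-panicle dimension errors are
  larger because partially occluded grains are genuinely truncated in
  the image.
* **Detector quality**: mAP50 of the reference detector on unoccluded
  grain fields.
* **Accuracy arithmetic**: the percentage computations used in
  classification reporting, evaluated from sample counts.

These sizes keep the full suite comfortably within a desk-scale run
while leaving the statistics stable across seeds.

## Numerical choices and edge cases

* Rounding of corrected counts: half away from zero, clamp at 0; both
  float and integer are reported.
* Longest-path ties: lexicographically smallest endpoint.
* `px_to_mm` is exactly linear; rectangle sides are exact for the hull
  vertex set (shapely's rotating calipers), quantization only enters
  through rasterization.
* Degenerate inputs raise typed errors (`DomainError`,
  `SegmentationError`, `CalibrationError`, ...); the batch driver
  converts them to per-image reason codes instead of aborting.
* MAPE refuses zero actual values rather than skipping them; R² refuses
  constant actual series; AP refuses empty ground truth.
* All randomness flows from explicit seeds; per-image seeds derive from
  the master seed through `numpy.random.SeedSequence` and stay below
  2³¹.

## Known limitations

* The density heuristic is a single occupancy feature; its accuracy
  (~86–96% on synthetic classes) bounds fully automatic counting. The
  override hook exists for exactly this reason.
* Grain width is measured from a 2-D projection; grains lying at an
  angle to the image plane would be under-measured in real photographs.
* The length smoothing window (9 px) trades residual staircase bias
  against curvature flattening; very tightly curled panicles would be
  slightly under-measured.
* The verbatim Hunter lightness variant is provided for comparison only;
  its YI scale is incompatible with the staging bands.
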