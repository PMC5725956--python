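# Methods

## Shape representation

The pipeline's central object is a simple closed polygon whose vertices are
organ boundary points, held in the image frame (x right, y down).  Organs
are photographed base-up, so the base is the topmost contour point
(minimum y) and the apex the bottommost; every descriptor relies on that
single convention.  Vertices are stored so the shoelace signed area is
positive; the polygon carries its pixels-per-cm calibration with it.

Boundary extraction is marching squares at the 0.5 iso-level of the padded
binary mask, i.e. the boundary runs along pixel edges at half-pixel
resolution.  Sub-pixel boundary schemes were deliberately not used: the
pixel-edge trace is simple, deterministic, and its systematic errors are
corrected by the smoothing step rather than hidden inside the tracer.

### Smoothing and resampling

Rasterized boundaries are stair-stepped, which inflates perimeter (a
pixel-edge trace of a disc overestimates the circumference by ~27%) and
destabilizes curvature.  The boundary is therefore smoothed with a
*circular* moving average (window = max(3, round(window_frac · n)) vertices,
forced odd; circular so the base/apex are not edge artifacts) and resampled
to exactly `n_out` vertices at uniform arc-length spacing.

Defaults `window_frac = 0.01`, `n_out = 1000`: at the 150–200 px/cm scales
used throughout (a 2 cm organ spans 300–400 px), a 1% window removes pixel
ripple while leaving nipple-scale features (σ ≈ 0.15 cm) intact, and 1000
uniform vertices make index windows interchangeable with arc-length
windows.  Any low-pass replacement must preserve the same invariants
(area change < 0.5%, commutation with calibration).

### Orientation

`normalize_orientation` rotates about the centroid so the major principal
axis of the vertex set is vertical, choosing the rotation that puts the
wider end up (the base, for fruits and endocarps).  Nearly isotropic shapes
(principal-axis ratio < 1.05) are left as imaged with a warning — there is
no meaningful axis to align and the rotation would be noise-driven.  Leaves
are the exception: their base (petiole end) is the *narrow* end, so the
pipeline flips leaf contours after normalization (`flip_vertical`).

## Descriptors

* **MaxTrDiam** is the longest single horizontal chord anywhere across the
  shape — not the width at a fixed station.  It is found by a 1024-level
  scanline sweep plus local refinement.  Exact ties cannot occur on
  rasterized contours, so chords within 0.1% (relative) of the maximum are
  treated as tied and the tie resolves to the centre of the tied plateau.
  Without this, the equatorial width profile of a disc — flat to sub-pixel
  ripple — lets noise place the "widest" chord a few percent off the
  equator and corrupt VerSym/TrSym.
* **Extreme points** (apex, base, tip) use the same plateau-centring: all
  vertices within 10⁻⁴ of the height of the extreme count as tied and the
  centre of the contiguous tied run is the anchor.
* **O**, the reference point for VerSym and MinCntTr, is the intersection
  of the widest chord with the vertical line through the midpoint of the
  A–B segment.  (Whether the original convention used the A–B midline or
  the centroid vertical is not decidable from the published material; the
  A–B midline is used, and the two coincide for symmetric outlines.)
  VerSym is measured from the apex end; `ver_sym_from_base=True` flips the
  reference end.
* **Circ** = 4πA/P², the classical isoperimetric quotient (1 for a disc).
* **Ellipse axes** come from the moment-equivalent ellipse (4·√eigenvalues
  of the region's covariance): deterministic, no iterative fit, exact for
  true ellipses.
* **Curvature** at a vertex is 1/R of the circumscribed circle of the
  vertex triple (i−s, i, i+s), s = max(1, len//15) within an extreme arc
  (default arc extent: 5% of the contour).  Exact on circles, zero on
  lines.  Units are cm⁻¹ on calibrated contours; note that curvature-like
  values reported per pixel at scanner resolutions are three orders of
  magnitude smaller, so cross-study comparisons must normalize units.

## Nipple detection

A nipple is a protrusion *set off from the fruit body*, not merely the
most curved point of the outline — an elongated plain fruit has an apex
curvature several times its body median.  Detection therefore works on the
signed curvature profile (neighbour spacing 2% of the contour):

1. walking outward from the apex B on each side, the first local minimum
   with prominence ≥ 0.5 × median |κ| is a *shoulder* (E, F) — the
   protrusion/body junction, often locally concave;
2. a nipple is declared iff both shoulders exist inside the search window
   (25% of the contour centred on B) and the curvature peak between them
   is ≥ 3 × median |κ|.

Geometry follows from the arc E–B–F and its chord: height = perpendicular
distance from B to the chord, area = region between arc and chord, plus
the arc length.  Detection is monotone in protrusion height and in the
threshold (lowering it never switches a detection off); borderline
profiles resolve by threshold, never by exception.

The spacing and prominence defaults are calibrated on the synthetic
bump family: at 120–200 px/cm, residual ripple on plain elongated
ellipses produces spurious minima with prominence up to ~0.16 × median,
while genuine bump shoulders reach ~3 × median — a margin of an order of
magnitude on either side of the 0.5 default.  The curvature-ratio
threshold itself (3.0) has no published reference value; both knobs are
exposed in `FruitParams`.

## Leaf petiole split

The width profile w(y) (longest single chord per station, 512 stations) is
scanned from the base: the petiole is the maximal contiguous run with
w < 0.15 × max width, provided it lasts ≥ 2% of the height (the minimum-run
rule keeps the naturally narrow tip region of a petiole-free blade from
being mistaken for a stalk).  The raw run, however, ends only where the
*blade* widens past the threshold, which for narrow stalks overcounts a
cap-shaped sliver of blade; the cut is therefore pulled back, within the
run, to the flare point — the first station whose width clearly exceeds
the stalk's own median width (max(1.25 w_stem, w_stem + 0.1·(w_cut −
w_stem))).  This drops worst-case petiole-area error from ~25% to ~10%
across stem widths of 0.06–0.15 cm.  The blade is the polygon clipped at
the cut line; blade height + petiole height equals total height by
construction.

Shape descriptors (area, width, shape index, symmetries, ellipse axes, tip
curvature) are computed on the blade so a long stalk cannot inflate them;
height, perimeter and circularity describe the whole leaf; the "position
of the width" is VerSym of the blade.  The emitted leaf record has 16
scalars.

## Endocarp sculpture (vertical view)

* **StArConv** = polygon area / convex-hull area (≤ 1; a roughness proxy).
* **Centre distances**: exact point-to-segment minimum and vertex maximum
  from the area centroid.
* **Inscribed circle**: the clearance field (signed distance to the
  boundary) is maximized by a coarse 64×64 interior grid, keeping up to
  five well-separated seeds (the field is multimodal on L-shaped or
  bilobed outlines), each refined by a shrinking 3×3 grid walk to a step
  below 0.05% of the bounding-box diagonal.  A medial-axis library would
  do the same job; the grid search was chosen to stay independently
  checkable against a brute-force distance-transform oracle.
* **Minimum bounding circle**: Welzl-type incremental algorithm over the
  contour vertices (the polygon's extreme points are vertices), exact to
  machine precision; input order is pre-shuffled with a fixed seed purely
  for the expected-linear running time, so results are deterministic.
* **Groove depths**: for each convex-hull edge, the pocket depth is the
  maximum perpendicular distance from the edge to the contour vertices
  between its hull endpoints.  Max depth is taken over all pockets; mean
  depth averages pockets deeper than a floor (0.5% of the bounding-circle
  diameter) that excludes rasterization micro-pockets.  Averaging over
  pockets rather than over all hull edges (zeros included) is a choice;
  with the per-edge convention mean depths scale down by the fraction of
  non-pocket edges.  Grooves are measured against hull edges, not radially,
  because grooves need not face the centroid.

The vertical-view record carries 22 scalars (13 common descriptors + 9
sculpture descriptors including groove count and perimeter convexity);
positions A and B carry 11 common scalars each.  The fruit record carries
24 core scalars (13 in position A + NippleIdx + 10 in position B), with
the nipple's height/area/arc length as supplementary columns.  These
groupings reproduce the published parameter counts; the exact original
enumerations were not published, so the assignment of individual scalars
to blocks is this package's own.

## Statistics

Per trait: group mean ± SE (SE = sd/√n, sample sd), fixed-effects one-way
ANOVA computed from the textbook sums of squares, and Tukey–Kramer
honestly-significant-difference comparisons — pair (i, j) is distinct when
|m_i − m_j| / √((MS_within/2)(1/n_i + 1/n_j)) exceeds the studentized-range
quantile q(1−α; k, N−k) (scipy's `studentized_range`, so any k and N).
The ANOVA shares MS_within with the Tukey rule by construction.  With
k = 2 the rule reduces exactly to the pooled t-test (q = t·√2).  Traits
are analyzed per imaging position; missing values (e.g. nipple geometry of
nipple-free specimens) are excluded listwise per trait.  Zero within-group
variance with unequal means yields p = 0 with a warning; with equal means
it is degenerate and raises.  No multivariate analysis is performed — each
trait is judged on its own discriminative power.

## Synthetic fixtures: what they do and do not show

The generator rasterizes analytic boundaries (4096 vertices, scan-fill, no
anti-aliasing so mask semantics are exact) of four families — ellipse
fruits, ellipse + Gaussian-apex-bump nippled fruits, sinusoidally grooved
discs, ellipse-blade + rectangular-petiole leaves — plus random Fourier
blobs for property tests.  Every fixture carries ground-truth descriptor
values computed from the generative parameters by closed form (πab,
elliptic-integral perimeters, π(R² + amp²/2), R ∓ amp, …) or quadrature,
never by the pipeline under test.  Organ colour is dark olive-green on a
light-blue board (the background colour the imaging protocol found most
effective), so the fixtures exercise real HSB thresholding; both colours
are configurable.

The fixtures emulate geometry and calibration, not photography: no
shadows, gloss, texture, chromatic noise or lens distortion, and exactly
one organ per frame.  Passing tests therefore establish the correctness of
the geometry and statistics stages and the noise robustness of the
detectors down to ~120 px/cm rasterization, but say nothing about
segmentation quality on difficult real photographs — on real data the HSB
box remains a per-session user choice.

Default study conditions used by the test-stage simulations: rasterization
at 120–200 px/cm (≥ 600 dpi equivalent for cm-scale organs); nipple bump
ladder 0–0.5 cm (σ = 0.15 cm) on a 1.5 × 1 cm fruit; petiole grid
0.4–1.2 cm × 0.06–0.15 cm on a 4 × 1.6 cm blade; grooved discs R = 1 cm,
amp 0.04–0.12 cm, 8 grooves; statistics at k = 7 cultivars × n = 25
specimens with per-cultivar means/SEs taken from the published shape-index
table, and 1000 (type-I error) / 100 (discrimination) replicates.  These
sizes keep a full run on one CPU in minutes while leaving every tolerance
limited by the method, not by sampling.

## Known limitations

* Cultivar discrimination from summary statistics is power-limited: with
  n = 25 and the published shape-index dispersions, the Tukey–Kramer
  critical difference (~0.06) is of the same order as the closest
  between-cultivar gaps, so normal-theory resampling typically separates
  18–19 of 21 cultivar pairs rather than 20–21.  The package reports the
  honest rate; see the acceptance output.
* One organ per image; multi-object frames must be cropped upstream.
* The HSB box is supplied, not learned; strongly shadowed or low-contrast
  backgrounds need a better box or pre-binarized input.
* Contours must be star-shaped enough for the apex/base convention to make
  sense; deeply re-entrant outlines (beyond endocarp grooves) are out of
  scope.
* Colour traits and 3D shape are out of scope.
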