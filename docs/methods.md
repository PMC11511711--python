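# Methods

## Scope and model

`shgmorph` quantifies fibrillar collagen in 2-D SHG microscopy images.
The underlying model of the data is simple: an SHG image of interstitium
is a dark background plus bright, ribbon-like fibers, so its intensity
histogram is a two-component mixture, and the collagen class — once
binarized and skeletonized — is a planar network of curvilinear fibers
that occasionally cross. All eight morphological features are functionals
of (a) the binary mask and (b) the fiber network extracted from its
skeleton, expressed in physical units through the pixel pitch (default
0.554 μm/pixel).

## Segmentation

A two-component 1-D Gaussian mixture is fitted to the pooled pixel
intensities by EM.

* **Initialisation** is deterministic: the Otsu threshold splits the
  histogram and each side is moment-matched (means, SDs, weights). No
  random restarts; a given image always yields the same fit. Side SDs
  are floored at 5 % of the pooled SD to avoid near-degenerate starts.
* **Convergence**: per-pixel log-likelihood improvement < 1e-6, cap 500
  iterations (standard and cheap at the 271² pixels of one region). The
  per-iteration log-likelihood path is stored and is non-decreasing, a
  property the test suite asserts.
* **Labeling**: pixel → collagen iff the posterior of the higher-mean
  component ≥ ½; the comparison is made on weighted log-densities, which
  is exact, and the tie (posterior exactly ½) goes to collagen.
* **Degenerate inputs**: a constant image raises a dedicated error; the
  pipeline-facing `segment()` converts it to an all-background mask.
  8-bit and 16-bit inputs are treated identically after casting to float;
  the mask is invariant to affine intensity changes (shift, positive
  scale), which the suite checks.

## Fiber-network extraction

The mask is reduced to a 1-px 8-connected medial skeleton
(`skimage.morphology.skeletonize`). The skeleton-pixel graph (diagonal
edges pruned when a cardinal stepping stone exists, so junction degrees
are not inflated by pixel triangles) is decomposed into branches between
node pixels (degree ≠ 2); closed degree-2 chains become loops.

Digital skeletons resolve an X-crossing of two thick ribbons as two
nearby degree-3 pixels joined by a short bridge rather than one degree-4
pixel. Bridges of arclength ≤ `merge_junction_px` (default 4 px, about
one ribbon width) between junction pixels are therefore absorbed into a
single junction cluster. At each cluster, every incident branch end gets
a tangent from a least-squares line over its 5 nearest vertices, oriented
away from the junction; branch-end pairs whose continuation turn
(180° minus the angle between outward tangents) is strictly below
`max_turn_deg` (default 60°, a conventional continuation limit in
fiber-tracking) are joined greedily, smallest turn first, ties broken by
terminal-coordinate lexicographic order; each end joins at most once.
The strict inequality makes the symmetric boundary case — three branches
at mutual 120°, turn exactly 60° — a non-join. Joined chains are glued
through the cluster along a shortest pixel path, so crossing fibers share
cluster pixels. Fibers shorter than `min_len_px` (default 5 px ≈ 2.8 μm,
the scale of skeletonization spurs) are discarded, and each fiber is
serialized from its lexicographically smaller endpoint.

**Cross-links** are detected on the full-resolution chains: any pixel
belonging to ≥ 2 fibers. A crossing leaves a small 8-connected patch of
shared pixels, so for counting, each maximal 8-connected component of
shared pixels is one cross-link point.

**Vertex spacing.** Chains traced on a pixel grid quantise steps to
{1, √2} and overestimate true arclength by up to ~8 % depending on
orientation, which would push chord/arc straightness several hundredths
below its true value — more than the effect sizes of interest (the
reference groups differ by 0.004–0.017). The default therefore simplifies
each chain with a Douglas–Peucker pass at 0.75 px tolerance (slightly
above the ≤ ~0.7 px excursion of a digital straight line), pinning
endpoints and cross-link vertices. Fibers then carry sparse vertices;
`simplify_tol_px=0` restores raw chains whose consecutive vertices are
exact 8-neighbours. Because width is a property of the fiber path rather
than of vertex placement, the width feature densifies the polyline back
to ≤ 1 px spacing before sampling the distance transform (sparse vertices
alone would over-weight fiber ends, where clearance shrinks into the
tip).

## Features

Definitions are literal: width is the vertex-to-nearest-background
distance (a radius-like quantity, not doubled into a diameter), computed
from the exact Euclidean distance transform; cross-link spacing is
arclength along the fiber between adjacent cross-links (vertices closer
than 3 px along a fiber belong to one junction traversal and merge to
their mean position — crossings below the junction scale are below the
method's resolution), averaged over fibers with ≥ 2 cross-links; features
undefined for a region propagate as NaN.

The orientation index works on the binary mask: mean-subtract, Hann
window, 2-D power spectrum, zero a DC disc of radius 2 px, form the
second central moment matrix of spectral power and take
`1 − sqrt(λ₂/λ₁)` (axis lengths are square roots of the moment
eigenvalues). The index is 0 for circularly symmetric masks, > 0.9 for
parallel stripes, approximately translation-invariant (the window breaks
exactness) and exactly invariant under 90° rotation. Its absolute values
between those limits depend on the full spectral shape, so it is
calibrated in tests by its limits and by monotonicity in the generator's
angular concentration, not against the centerline orientation tensor.

## Statistics

Per-group mean ± sample SD (n−1), one-way ANOVA (scipy), and Tukey HSD
(scipy) for the six pairwise comparisons, starred * p < 0.05, ** p < 0.01,
*** p < 0.001. ANOVA requires ≥ 3 groups with ≥ 2 observations each.
The post-hoc method is an assumption: the reference analysis names only
ANOVA while showing pairwise stars, and Tukey HSD is its standard
companion. The default unit of analysis is the region; because the 6
regions per ROI are not independent specimens, `unit="specimen"` first
averages regions within specimen — the table carries specimen ids
precisely so users can avoid pseudo-replication.

## Synthetic fields

The generator emulates an interstitial region: a 150 × 150 μm square at
0.554 μm/pixel containing `n_fibers` wavy ribbons.

| parameter | default | why |
|---|---|---|
| length law | truncated normal, 15.403 ± 1.526 μm (floor 1 μm) | normal-group reference morphometry |
| n_fibers | 115 | 0.0051 fibers/μm² × 22 500 μm² |
| waviness (chord/arc) | 0.897 | normal-group straightness |
| orientation | von Mises on the doubled angle, κ = 8, mean 0° | strongly aligned, axial data |
| width_px mixture | {2: 0.745, 3: 0.255} | calibrated so the exact-EDT width oracle is 1.501 μm under the default law |
| noise | bg 10, Gaussian SD 6, Poisson gain 1, signal 110 | ≥ 5-SD class separation; the reference instrument's noise statistics are uncharacterised, so this is a plausible stand-in, not a calibration |

Waviness is realized as a half-sine arch orthogonal to the chord whose
amplitude is solved by bisection until chord/arc matches the request to
1e-4 — one parameter, analytically checkable (the solver reproduces the
semicircle's 2/π to 1e-3). Fiber midpoints sit on a jittered √n × √n
grid; `crossing_rate` is a qualitative disorder dial (0 enforces ribbons
that touch nothing, larger values increase jitter), and the crossings
actually achieved are measured from centerline–centerline intersections
(shapely) and recorded — never assumed from the request. Fibers are
placed entirely inside the region so their ground-truth lengths are
measurable after extraction. Ribbons are rasterized by snapping the
centerline to its pixel chain and thresholding the chain's distance
transform at `width_px`; snapping keeps digital half-widths exact, and
the resulting stadium ends have the centerline as their medial axis. A
flat-cap variant (exact pixel counting, ragged skeleton ends) exists for
tests. All randomness derives from one root seed through counter-keyed
`SeedSequence` streams, so output is bit-reproducible and adding a draw
kind cannot perturb others.

`analytic_features` is a fully image-processing-free oracle: lengths,
straightness and orientations from the centerlines, cross-links from
exact geometry, and width from an exact distance transform of each
fiber's isolated ribbon (`analytic_fiber_width_um`) — for diagonal runs
the digital ribbon is slightly thinner than the axis-aligned
`width_px + 1` pixels, and the oracle reflects that.

What the phantom does **not** emulate: partial-volume intensity at fiber
edges, depth-dependent scattering, fiber bundles and branch points (as
opposed to crossings), 3-D projection effects, or cellular TPEF signal.
Passing recovery tests therefore demonstrates the correctness of the
measurement chain on fields with known geometry, not segmentation
robustness on degraded tissue images.

## Validation experiments and problem sizes

`shgmorph.validation` (reported by `scripts/acceptance.py`) runs four
recovery experiments, each pushing seeded regions through the full
pipeline: mean fiber length and mean straightness on 50 wavy, low-crossing
regions of 40 fibers; mean width on 50 straight-ribbon regions whose
two-width mixture is calibrated at run time so the exact-EDT oracle
equals 1.501 μm under the experiment's orientation law; and mean
cross-link spacing on 30 jittered perpendicular grids with exact 10.023 μm
line spacing (grid phase and rotation random, the spacing itself never
jittered — it is the ground truth). Forty fibers per region keeps
individual fibers identifiable, which is what parameter recovery
requires; at the full reference density (115/region) aligned ribbons
frequently touch laterally and merge, biasing counts and lengths — a
genuine resolution limit of skeleton-based tracking at high packing
fraction, shared by the tissue measurements themselves. The whole
validation run takes ~1 minute on one CPU.

## Known limitations

* The crossing-rate dial produces far fewer realized crossings than
  "expected cross-links per fiber" would suggest for aligned fields;
  crossing-controlled truth should use the grid constructor.
* Junction clusters wider than `merge_junction_px` (very thick fibers)
  can still split a crossing into two junctions and break a fiber.
* Cross-link spacing inherits a small positive bias (~5 % at 10 μm
  spacing) from pinned junction pixels adding zig-zag arclength between
  crossings.
* The FFT orientation index compresses toward small values for short,
  wavy fibers (broad spectra); only its ordering and limits are
  meaningful across conditions.
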