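# Methods

This note records the models, algorithms and numerical choices behind
`sprouttrack`, the assumptions they rest on, and what the synthetic
validation does and does not establish.

## Problem setting and coordinate conventions

A sprouting region in a microfluidic device is imaged daily by phase
contrast.  The endothelial monolayer lies along the bottom edge of the
canonical image; sprouts grow upward (toward decreasing row index) into
the collagen gel, which is bounded laterally by trapezoidal PDMS posts.
All graph coordinates are `(x, y)` with `x` = column and `y` = row,
0-based; "nearest the monolayer" therefore means largest `y`.  Images are
indexed `[row, col]`.

## Preprocessing

**Stitching.** Adjacent tiles of one time point are aligned by
scale/rotation-invariant keypoints (SIFT), ratio-tested descriptor
matches, and RANSAC similarity estimation (3-point samples, 1 px residual
threshold, 500 trials); a pair with fewer than 8 inliers fails loudly.
Overlaps are averaged.  Any invariant detector serves here — the method
only needs correspondences.

**Registration.** The posts are the only structures guaranteed static
across days.  They are detected as compact dark components near the
lateral borders (components touching the border are discarded: their
centroids are clipped and unreliable), each represented by Hough-normal
edge lines and its centroid.  Centroids are matched across frames by
nearest neighbour after removing the median displacement, a similarity
transform is fit by least squares, and correspondences with residuals
above `max(2 px, 3×median)` are dropped and the fit repeated.  On rendered
phantoms this recovers injected misalignments of ±7 px / 2° / 1% scale to
better than 0.1 px and 0.05°.  The first frame is the default reference.

**Gel region and segmentation.** The cell–gel interface is the top of the
bottom-anchored bright band in each column, fit with a least-squares
parabola under iterative 2.5σ outlier clipping (columns where a vessel
meets the monolayer pull the edge point upward and are rejected); with
fewer than 5 edge points a horizontal fallback at the band top is used.
The global Otsu threshold is computed over the whole image minus the
posts — the monolayer band guarantees a bimodal histogram even in early
frames whose sprouts are tiny — and applied within the gel region,
retracted 3 px below the fitted interface to absorb its raggedness.
Cleanup follows the standard order: closing (disk radius 2), hole
filling, erosion (disk radius 2 by default; radius 1 is appropriate for
thin vessels ~12 px wide, and is what the end-to-end benchmark uses), and
area opening at 50 px².  A near-unimodal histogram (class-mean separation
< 25 gray levels) yields an empty mask with a warning rather than noise.

## Skeletonization

**Distance transform.** `T` solves the eikonal equation `|∇T| = 1` with
`T = 0` on the object boundary, marched inward in order of increasing
distance (a fast-marching front).  Each accepted pixel carries the
boundary pixel its front originated from, and `T` is the Euclidean
distance to that origin.  Carrying origins keeps the solution sharp
across shock lines (where fronts collide — exactly the skeleton), where
plain first-order upwinding smears; measured against the exhaustive
min-over-boundary-pixels oracle the error is below 1 px on every random
mask tested (and typically 0).

**Boundary parameterization.** The outer boundary of each object is
traced in order (Moore neighbourhood, Jacob's stopping criterion), holes
filled first so only the outer contour is parameterized.  The trace index
becomes `U` on the boundary (an arbitrary start pixel gets `U = 1`), and
interior pixels inherit the `U` of their origin.  Because the start pixel
is arbitrary, `U` differences are always taken circularly,
`min(|ΔU|, L − |ΔU|)` with `L` the boundary length — otherwise the seam
would read as a false discontinuity of magnitude ≈ `L`.

**Skeleton detection.** A pixel is skeletal iff its circular `ΔU` to some
8-neighbour exceeds `u_threshold` (default 15 px of arc length; boundary
features shorter than roughly twice the threshold produce no skeleton
branch).  Of the two pixels straddling a discontinuity, the one with the
larger `T` is marked — it lies nearer the true medial axis; exact ties
mark both.  The detected set is thinned to single-pixel width; thinning
can retract branch tips by a pixel or two, so endpoints are re-grown
along detected-but-removed pixels with non-increasing `T` (preserving
single-pixel width), and components under 3 px are dropped.  On a
rectangle this skeleton matches the analytic medial axis (central segment
plus corner diagonals) within 1 px Hausdorff distance.

**Graph construction.** Skeleton pixels with one neighbour are end nodes;
clusters of adjacent pixels with ≥ 3 incident paths merge into one branch
node at their centroid (ids in raster order).  Segments are traced
between nodes; radii are sampled at `N_eq = 11` equidistant arc-length
points as the interpolated `T` plus a **+1.0 px correction**: the
continuous boundary lies ~0.5 px beyond boundary-pixel centres, and the
thinned skeleton pixel sits ~0.5 px off the true axis on average, which
the minimum-distance reading loses.  Measured on tubes of radius 3–10 px
the raw `T` bias is −1.0 ± 0.3 px; corrected, mean radius errors stay
within 0.35 px.  Eleven samples balance accuracy against cost; more
samples sharpen width estimates linearly in time.

Each connected component of at least 50 px is skeletonized independently
and the graphs merged — distinct sprouts are disjoint objects, and the
boundary parameterization is only defined per object.

## Specious-segment classification

Features per segment: arc length `l`, extreme radii `r_max`, `r_min`, and
connection type `J` ∈ {branch–branch = 0, branch–end = 1, end–end = 2}
from the endpoint roles (junction and base endpoints count as vessel-body
continuations, i.e. like branch endpoints).  Features are standardized —
their scales differ by orders of magnitude — and classified by a linear
soft-margin SVM (`C = 1`).  The labeled experimental templates behind the
original classifier are not distributed; the shipped synthetic set (214
vessel / 102 spur templates, matching that class balance) is linearly
separable by construction, with radii the separating coordinates
(vessels ≥ 3 px, spurs ≤ 2.5 px) and `J` only weakly informative.
Crucially, end–end templates appear among the positives: an unbranched
sprout *is* an end–end segment, and a set without them teaches the
classifier to prune plain trunks.  Five-fold stratified CV on the shipped
set is exact (1.0); with 10% flipped labels it stays above 0.85.  After
pruning, degrees are recounted and roles relabeled: a false branch node
that loses its filopodial stub becomes a junction node.

## Base nodes and routes

Per connected component, the node `A` nearest the monolayer is examined.
If `A` is an end node with no branch node within `d_base = 20 px`, it is
the base (scenario: one sprout).  Otherwise the nearby branch node `B`'s
other neighbours are tested with the rise/run ratio `|Δy|/|Δx|`; a
neighbour whose segment to `B` is flatter than `τ = 0.5` (≈ 27° from
horizontal) marks an artificial connector — a leftover of the cell–gel
interface joining two sprouts — which is removed, the neighbour becoming
the second base.  A junction `A` is tested on its own two neighbours the
same way.  Ties at exactly `τ` count as genuine vessel (strict
inequality).  The degree-3 case is the canonical procedure; nodes of
higher degree are handled by testing every neighbour.  If `A` is itself a
branch node (not covered by the procedure) it is taken as the base and
logged.

Routes are arc-length-weighted shortest paths from each base to every
reachable end node; pruned sprout graphs are trees, so any positive
weighting yields the same node sequences.  Routes never pass through
another sprout's base; unreachable end nodes are warned about and
skipped.  Branch length is the summed arc length; width is twice the mean
sampled radius.

## Tracking

**Sprouts** (route groups sharing a base) are matched between consecutive
frames by mean x-position — distinct sprouts do not overlap, so their
skeletons separate cleanly in x.  Matching is one-to-one via the same
assignment machinery; ties break toward smaller x.

**Branch nodes** within a matched sprout pair are matched by the
Hungarian method on their pairwise Euclidean distance matrix `C`.  When
the later frame has more nodes (`n₂ > n₁`, branches forming), `C` is
padded to square with a constant `c0 = max(C) +` image diagonal —
strictly larger than every real distance yet well conditioned — and
columns assigned to padded rows are new nodes.  The solver is
`scipy.optimize.linear_sum_assignment`; its optimality is enforced in the
tests by a brute-force permutation oracle up to n = 7, along with the
row/column-sum constraints and the reduction invariance (subtracting a
constant from a full row or column never changes the optimum).  A frame
with *fewer* branch nodes (retraction) is outside the model's assumption;
it is handled by transposed padding, flagged as terminated, and warned
about rather than failing.  Segments incident to matched node pairs are
matched by mean x (near-equal x resolved by mean y); segments incident
only to new nodes open new branches.

**Branch identity roll-up.** A branch only elongates between daily
frames, so its old route is a geometric prefix of its new route.  Branch
continuation is decided by optimal assignment on a prefix-agreement
score: the mean distance between the old polyline and the new one
truncated to the old arc length, plus half the mean deviation of the new
growth from a straight continuation of the old terminal direction (the
term that separates the two arms of a fresh fork, both of which contain
the old route as a geometric prefix — the arm that keeps the old heading
continues the branch, the deviating arm is the newborn).  Scores above
20 px open a new branch instead.  This geometric roll-up states at route
level what the node/segment correspondence states pointwise, and is
robust to the frame-to-frame topology flicker of skeletons extracted from
noisy segmentations.  The worked two-day example reproduces the expected
table either way: branch 1 keeps `[1 2 3]`, branch 2 extends
`[1 2 4] → [1 2 4 5]`, and `[1 2 4 6]` is born at the new node 4.

The history table keys branches by persistent id; once opened a branch is
extended every frame it is re-identified, and its route, tip position,
length and width per frame are recorded.

## Tip/stalk identification and reporting

Cell positions come from an external tracker as CSV; the package never
detects cells.  For each branch, the `N_tip = 3` cells nearest the last
segment's end point are candidates (tip plus its two trailing stalk
cells; all cells if fewer), and the tip is the candidate maximizing the
projection `p = v_se · v_si / |v_se|` onto the segment direction — the
cell that has migrated farthest along the growth direction.  Projection
ties break toward the smaller end-point distance.  Distance-only
selection fails exactly on lateral configurations (nearest cell off-axis,
true tip ahead); the projection criterion does not, which the constructed
trap family exercises.  A cell proposed as tip by two branches goes to
the larger projection and the loser re-runs without it.  Branch
*membership* (for stalk labels and lineage) is distance to the route
polyline within 1.5× the local radius — candidacy and membership are
distinct notions, and only candidacy is defined by end-point distance.
Branches with no cell within `max(3×radius, 15 px)` of their end point
get no tip, with a warning.

Morphometrics are long-format tables (region, condition, frame, branch,
length, width, count) with mean ± SEM summaries; condition comparison is
one-way ANOVA with the star convention ns (> 0.05), * (≤ 0.05),
** (≤ 0.01), *** (≤ 0.001), **** (≤ 0.0001), boundaries inclusive
downward.  Lineage records combine branch ids, phenotypes, shared-trunk
and monolayer flags, and parent links taken verbatim from the input
table; the JSON records are the contract, the frame-by-frame ellipse
rendering is best-effort.

## Phantoms: what they emulate, and what they do not

The generator sweeps tubes along control-point centerlines anchored in a
monolayer band, with exact node roles, routes, persistent branch ids and
cell positions per frame.  Boundary "raggedness" is smooth noise whose
amplitude is a *bounded peak* (clipped at ±amplitude), not a Gaussian σ —
segmentation noise perturbs a vessel outline; it does not pinch the tube
off.  Renderings draw foreground/background from Gaussians 60 gray levels
apart with σ = 10 (strong bimodality, so thresholding is well posed),
trapezoidal posts inset 14 px from the lateral borders, and per-frame
camera jitter applied to the whole scene after drawing and before sensor
noise.  Distinct sprouts must sit ≥ 3 tube diameters apart in base x and
may not overlap (enforced, since the tracking model assumes it).
Time-lapse growth is monotone at `elongation_per_frame`; scripted forks
occur where the parent's tip sat the previous frame, so both arms carry
one frame of growth past the fork; sprouts curve gently (heading noise
σ = 0.06 rad per 5 px step) and children fork 30–45° toward open gel —
branching happens where there is space.

The end-to-end benchmark is 20 regions × 6 daily frames, 300×400 px,
radius-6 tubes, 30 px/frame elongation, one fork per sprout on days 2–4,
2 px peak raggedness, jitter up to ±5 px / ±1.5° / ±1% scale.  A detected
trajectory identifies a true branch when their births agree within one
frame and tips agree within 15 px in every common frame, one-to-one.
Precision and recall on this benchmark are ≥ 0.95/0.90 (typically ≈ 0.98).

What passing does **not** show: the phantoms have no phase-contrast halo,
no uneven illumination, no cell-body texture, no anastomosis (loops), no
branch retraction, and no genuinely ambiguous vessel/filopodium boundary —
the classifier's real-world accuracy depends on real labeled templates,
for which the CSV loader exists.  Phantom results bound the pipeline's
algorithmic errors, not its robustness to imaging physics.

## Known limitations

- Anastomosis is out of scope: pruned sprouts are assumed acyclic, and
  branch *merging* across frames is not modeled.
- Retraction (fewer branch nodes in the later frame) is flagged, not
  tracked.
- Sub-pixel skeleton localization is not attempted; node positions are
  pixel-centroid accurate.
- The scripted growth model extends tips with seeded random headings, so
  phantom "biology" is purely kinematic; no chemotaxis or cell mechanics.
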