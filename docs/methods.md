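# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic validation does and does not
demonstrate.

## Synthetic scenes and their ground truth

A scene is a square ground patch at z = 0 (non-plant color), a vertical
stem cylinder sampled volumetrically (point count Poisson with mean
π r² h ρ, matching the stem-contamination formula used by ground removal),
and N leaves. A leaf is the region (u/a)² + (v/b)² ≤ 1 (optionally a
superellipse with exponent p) wrapped onto a cylinder of radius Rc so that
the midrib subtends the bend angle θ. Two facts make the ground truth
exact:

* wrapping a flat sheet onto a cylinder is an **isometry**, and
* the midrib coordinate is scaled by the constant s = Rc·θ / (2a) before
  wrapping, so the true leaf length is exactly Rc·θ.

Hence the curved leaf's area is s·(flat outline area) and its perimeter is
the flat outline's with the u-axis stretched by s. Truths are computed by
quadrature (Simpson for area, a 200 001-point polyline for the perimeter;
doubling the resolution moves the values by < 0.01%), which for the
ellipse agrees with the closed forms (πab; 4aE(e²)) to 1e-6 relative.
Sampling is rejection sampling on the parameter rectangle — exact
uniform-per-area because the map's Jacobian is the constant s — followed
by isotropic Gaussian noise.

Defaults are chosen as plausible for close-range stereo capture of young
pepper-type plants: sensor noise σ = 0.3 mm, leaf sampling density
25 points/mm², stem radius 2 mm, leaf semi-axis ratio a : b = 2 : 1,
leaves attached ~12 mm off the stem axis (a petiole-like stand-off; pepper
petioles run 1–3 cm). What the generator does **not** emulate: self-
occlusion and partial scans, registration artifacts, venation and serrated
margins, color variation within an organ, non-planar terrain. Passing
tests therefore show that the pipeline recovers phenotypes from clean,
fully sampled, color-separable plants — not that it survives real capture
pathologies.

## Ground removal

The color rule is HSV-based: plant iff hue ∈ [70°, 170°] and saturation
≥ 0.15 (both configurable). RANSAC uses 500 iterations with early exit at
90% inlier fraction, then a least-squares refit on the winning inliers
(kept only if it does not lose consensus); removal applies only inside the
ground candidates' bounding box (padded by the distance threshold), so
elevated plant points are never tested against the plane. Tie-breaks are
first-found under the seeded sampling order. The threshold-sweep helper
reports inlier counts across thresholds with a fixed budget and no refit,
so the counts are comparable (and provably non-decreasing) across the
sweep.

## Segmentation

K-means is Lloyd's algorithm: seeded random choice of K distinct input
points, convergence when every centroid moves < θ (default 1e-3 mm),
empty clusters re-seeded with the point farthest from its centroid, and
10 seeded restarts keeping the lowest WCSS (5 during elbow scans). The
elbow scan runs on a uniform subsample of ≤ 8000 points — the knee is a
shape property of the curve, not of the point count — while the final
clustering uses the full cloud.

**Knee selection.** The knee is the interior k farthest below the chord
joining the endpoints of the normalized WCSS curve. An absolute
second-difference rule was considered and rejected: when several
well-separated clusters split one at a time the WCSS decays roughly
geometrically, and the second difference then always peaks at the first
interior k, underestimating K for any scene with ≥ 4 organs. The chord
rule agrees with the second difference on curves with a single sharp knee
(e.g. WCSS [100, 20, 18, 17] → K = 2) and resolves knee-free linear decay
to the smallest interior k.

Cluster-to-leaf matching for the Dice gate is greedy by overlap, each
reference leaf used at most once; unmatched leaves score 0. The threshold
schedule (0.88 / 0.84 / 0.80 by leaf count) follows the leaf-count bands
stated in the project's acceptance contract.

## Smoothing

Normals are PCA-plane fits over the 20 nearest neighbors, oriented away
from the cloud centroid; all normal angles are folded to [0°, 90°] so
orientation flips cannot masquerade as roughness. Angles are in degrees —
forced by the printed correspondences 30° ↔ 0.033 and 45° ↔ 0.022 — and a
perfectly smooth cloud (zero mean angle) returns the capped sentinel 1e6
rather than infinity.

MLS fits a quadric (degree-1 fallback below 6 neighbors) in the local PCA
frame of each point's ball; the fit is solved from normal equations with a
1e-10 ridge, neighborhoods capped at the 64 nearest within the radius.
Default radius is 4× the mean nearest-neighbor spacing, inlier distance
radius/10. The pipeline instead projects **every** point (inlier distance
0) and iterates 3 passes: single-pass MLS leaves point-to-point height
jitter of the same order as the fit noise (neighboring points project onto
slightly different local fits), which a triangulation then counts as
crumpled area (+15–40% in experiments at σ = 0.3 mm); three passes
converge to a smooth manifold and bring the meshed area within ~1% of
truth. The pipeline also grows the radius ×1.5 (up to 5 times) if some
point's ball cannot support a fit — noise tails sit farther out than the
spacing-derived default reaches.

The volume-ratio gate compares PCA-oriented bounding-box volumes as
smoothed/original against [0.7, 0.9]; on a failed gate the pipeline
re-smooths once with radius ×1.5 and keeps whichever result lies closer to
the band center. A perfectly planar leaf has zero box volume; the gate is
then skipped (ratio NaN) rather than failed. The PCA box is not the
minimal-volume box, which is irrelevant here because only the ratio of two
boxes of the same leaf is used.

## Measurement

The measurement plane is the leaf's own PCA plane by default; `plane="xy"`
reproduces projection onto the horizontal plane, and is the right choice
for bends approaching 180° where the PCA plane is ambiguous. Base and tip
are the extremes along the first in-plane principal axis; as landmarks the
package averages the 5 most extreme points, which damps the outward bias a
single noise-displaced extreme adds (~halves the length error on noisy
leaves, neutral on clean ones). Each chord division point keeps its
in-plane position and takes only its **height** from the surface (mean
height of cloud points within 1.5× the grid-equivalent spacing
√(hull area / n)); a flat leaf therefore measures exactly its base–tip
chord for every n₁, and lateral corridor jitter cannot inflate the
polyline. Division points over holes are skipped and bridged, with a log
note. n₁ defaults to 50; pushing n₁ far beyond the point spacing (e.g.
2000 segments over a 35 mm leaf) re-introduces corridor-membership jitter
and is not recommended.

Boundary extraction builds the 2D Delaunay triangulation of the projected,
uniformly downsampled cloud, keeps triangles with circumradius < α, and
walks the boundary edges into a loop (largest loop wins; clockwise viewed
against the plane normal). α defaults to 3× the grid-equivalent spacing
and, in auto mode, grows ×1.5 (≤ 6 times) until the outline closes —
Poisson gaps routinely exceed the nominal spacing. The downsampling
targets ~1500 points: finer boundaries zigzag along sampling jitter and
inflate the perimeter sum, coarser ones cut corners; 1500 sits near the
error minimum for leaf-sized clouds at realistic densities. Perimeter sums
the **3D** distances of the ordered boundary points.

Ball pivoting is implemented natively: seed triangles are sought among
unused points (ball of radius r touching three points and containing no
other), then the ball pivots around each front edge — candidate contacts
are gathered within 2r of the edge midpoint, both ball centers per
candidate are computed vectorized, and the first contact by rotation angle
wins; non-manifold attachments are refused and the empty-ball property is
re-verified per accepted triangle (shell tolerance 1e-7 relative). Radii
default to {2, 3, 4, 5}× the mean nearest-neighbor spacing, ascending;
edges that fail at one radius are re-queued for the next, which is what
fills sparse-region holes. Normals orient against the cloud's minor
principal axis — adequate for leaf-like sheets bending less than a quarter
turn, and a documented limitation for more extreme curvature. Exactly
cocircular configurations (perfect lattices) can produce overlapping
faces; sampled clouds in practice are never cocircular.

Scale factors μ₁ (length) and μ₄ (area) default to 1: coordinates are
treated as millimetres end to end, with no unit conversion anywhere.

## Pipeline and demo

Stages persist all artifacts (PLY/CSV/JSON) so each can be re-run in
isolation; the manifest records seed, parameters, per-stage counts and
timings (logged, never asserted). The pipeline's K range defaults to
[2, 10] — single-plant scenes carry a handful of organs, so scanning to 30
would waste the elbow search; the per-function defaults remain [5, 30].
Before measuring, each matched cluster is reduced to its largest connected
component (neighborhood radius 3× mean spacing): a Voronoi partition can
hand a cluster spatially detached stem segments or stray ground survivors,
which are not part of the leaf surface. Clusters without a reference label
are classified stem-like when the longest OBB axis exceeds 4× the middle
one, and only non-stem-like clusters are measured.

The demo models a young plant over three growth periods: three leaves
(semi-major 20 / 24 / 32 mm — increments chosen so the third exceeds the
second, the accelerating-growth pattern of early development) on a short
stem (25 / 30 / 35 mm), sampled at 12 points/mm² with σ = 0.3 mm noise.
The demo density is a problem-size choice to keep the three-period run
around two minutes; single-leaf validation runs at the full 25 points/mm².

## Known limitations

* Concave outlines finer than the alpha radius (serrations, lobes) are
  smoothed over; the perimeter of a strongly serrated leaf is a lower
  bound.
* The smoothness statistic depends on the normal-estimation neighborhood
  (fixed at 20); values are comparable within this package, not across
  tools with other conventions.
* K-means segments by Euclidean proximity only: organs that interpenetrate
  (overlapping leaves, leaves hugging the stem) will exchange points, and
  the Dice gate is the detector for that failure, not a cure.
* Ball pivoting assumes consistent normal orientation; sheets bending
  beyond ~90° need externally supplied normals.
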