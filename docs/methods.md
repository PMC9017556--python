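# Methods

## Image model and preprocessing

Volumes are arrays ordered `(z, y, x)` with voxel-centered coordinates and
spacing `(dz, dy, dx)` in mm.  Intensities are tagged as raw CT values,
8-bit gray, or floating gray in [0, 255]; all internal arithmetic is
floating point and quantization (round-half-even) happens once, at 8-bit
export, to avoid double rounding in chained pipelines.

The window/level transform clamps at `X ≤ L − W/2` and `X > L + W/2` and is
linear in between; the point `X = L + W/2` itself maps to 255 via the ramp,
consistent with the strict upper inequality.  Trilinear interpolation
indexes its 8 corner values with subscript bits ordered `(z, y, x)` —
`f001` is the x=1 corner — and reproduces any polynomial multilinear in
(x, y, z) exactly, which is the property the tests pin down.  Slice
interpolation inserts `factor − 1` equally spaced slices through the same
kernel (pure z-interpolation makes it linear in z) and keeps original
slices bit-exact, so sub-sampling is a strict inverse.

Denoising is deliberately two-step rather than 3-D: a 1-D median along z
(window 5, clamped — shrunk, not padded — at the stack ends) exploits
inter-slice correlation and kills impulse slices; then each slice is
smoothed by weighted neighborhood averaging with reflect padding (default
3×3 uniform; 3×3 and 5×5 are the practical sizes).  Both steps are convex
combinations of input values, so the output range never exceeds the input
range and constants pass through unchanged.

## Level-set segmentation

Two data models share one contour engine.  The piecewise-constant (PC)
model scores a partition against global inside/outside means c1, c2 plus a
contour-length penalty ν|C| (discrete perimeter).  The local binary fitting
(LBF) model replaces c1, c2 with fields f1(x), f2(x) = Gaussian-weighted
local intensity fits,

    f_i = K_σ ∗ (M_i I) / K_σ ∗ M_i,   M1 = H_ε(φ), M2 = 1 − H_ε(φ),

with the denominator floored at 1e-10.  Because the fits are local, a
smooth multiplicative bias field is absorbed into f1/f2 and the data force
still vanishes only at true region boundaries; this is the model's reason
for existing, and the test suite demonstrates it directly (LBF beats PC in
Dice on a bias-confounded two-region phantom where the biased intensity
ranges overlap).

The evolution is the standard variational descent of the combined energy
with smooth Heaviside `H_ε(φ) = ½(1 + (2/π) arctan(φ/ε))`, its matching
Dirac `δ_ε = ε/(π(ε² + φ²))`, ε = 1, curvature `div(∇φ/|∇φ|)` with the
gradient magnitude floored at 1e-8, and distance regularization
`μ(∇²φ − div(∇φ/|∇φ|))` that keeps φ near a signed distance function
without re-initialization.  Convergence is declared when the foreground
mask changes by less than `tol` (fraction of pixels, default 1e-4) for 10
consecutive iterations.

Numerical choices that mattered in practice:

* **Curvature on flat fields.**  Where |∇φ| sits at the 1e-8 floor the
  gradient direction is float noise; normalizing it yields O(1) random
  curvature which ν·δ amplifies into spurious patch flips.  The normal is
  therefore zeroed there — a flat field has zero curvature.
* **Step size.**  The variable step reaches 3τ₀ in flat regions, so the
  explicit scheme needs 3τ₀·μ inside the 2-D diffusion stability bound
  (≈ 0.25).  The default is τ₀ = 0.02 with μ = 1: comfortably stable, the
  discrete global energy is then non-increasing per step on noise-free
  phantoms, and convergence takes fewer iterations overall than with a
  marginally stable larger step.
* **Initialization.**  φ starts as a signed Euclidean distance to the seed
  region boundary (positive inside).  A flat binary ±2 start leaves far
  homogeneous regions only weakly signed; the early data-force transient at
  the contour then propagates through the fitting convolutions and
  permanently flips their sign (there is no restoring force where f1 = f2).
  The growing distance magnitude suppresses δ_ε far away and confines the
  evolution to the contour band.  The distance profile is maintained by the
  regularizer thereafter.
* Intensities are min–max normalized to [0, 1] *only* for the variable-step
  field g(x), fixing the meaning of its 0.5 constant; the data terms see
  raw intensities, and the segmentation is invariant to adding a constant
  to the image (verified empirically).

Defaults: λ₁ = λ₂ = 1, ν = 0.003·255², μ = 1, σ = 3 px, τ₀ = 0.02, ε = 1,
max_iter = 500, tol = 1e-4.  ν is scaled for a [0, 255] intensity range; σ
sets the locality of the fits (larger σ → closer to the PC model, which
the suite checks in the σ → ∞ limit).

**Multi-class segmentation** runs one binary level set per tissue class:
class intensity centers come from seeded k-means on the lightly smoothed
image (k + 1 clusters; the darkest is background), each class is seeded
with its nearest-center pixel set, and final labels are the arg-max of the
converged φ fields (background where all are negative).  Constant images
short-circuit to all-background with a logged warning, since no data force
exists.  3-D stacks are segmented slice by slice.

## Ant-colony clustering segmentation

Each pixel carries a 3-feature vector: gray value V, Sobel gradient
magnitude G (responses divided by 4 so a unit intensity step produces a
unit-scale gradient — otherwise G dominates the feature metric and boundary
pixels misclassify), and the 3×3 neighborhood mean Ne.  Distances are
weighted Euclidean; the heuristic is η = b/d with b the clustering radius,
capped at d = 1e-9.

The method couples two ant behaviors.  Spatial walks: ants start at random
pixels and take inertial 8-neighbor steps with probability ∝ W(σ_i)·w(Δθ),
where W(σ) = (1 + σ/(1 + δσ))^β is the two-parameter pheromone weighting
and w(Δθ) the turn-angle table {0°:1, ±45°:0.5, ±90°:0.25, ±135°:0.1,
180°:0.05}; each step deposits T = n₀ + p·Δh into the pixel field, with Δh
the window-similarity (mean/std/histogram mix, weights summing to 1, each
term normalized by its maximum over the current cycle's evaluated pairs,
0/0 → 0).  Cluster assignment: pixel→center probabilities
∝ τ^α·η^β; the pheromone links decay by ρ per cycle and are reinforced by
the *expected* assignment traffic scaled by W(σ) at the pixel —
expectation rather than sampled hard assignments keeps the reinforcement
noise-free and the run deterministic apart from the seeded walks.  Centers
are recomputed as responsibility-weighted feature means; final labels are
the arg-max rule, relabeled in increasing gray order so outputs are
comparable across runs.  Defaults: α = 1, β = 2, ρ = 0.9, δ = 0.2,
n₀ = 0.1, p = 1, 50 ants × 100 steps, 30 cycles, 3×3 windows.

FCM (fuzziness m = 2) and KFCM (Gaussian kernel, bandwidth = intensity
std) are implemented in-package with deterministic quantile initialization;
k-means delegates to scikit-learn.  All three cluster raw intensity only.

## Tetrahedral meshing

Bowyer–Watson insertion: all tetrahedra whose circumsphere contains the new
point form the cavity (restricted to the connected component containing the
point); the point is joined to every cavity boundary facet.  The cavity is
*repaired* before retriangulation: every boundary facet must see the point
strictly on the same side as the cavity tet it bounds, else the neighbor is
absorbed.  This matters because insertions also happen after constraint-
recovery flips, when the mesh is no longer Delaunay and the raw insphere
cavity need not be star-shaped; connecting to an unrepaired cavity creates
overlapping elements.

Predicates (orientation, insphere) are evaluated in extended precision
with a relative error filter (1e-10 scale); values under the filter are
recomputed exactly in rational arithmetic (floats are dyadic rationals),
so signs and exact-zero ("on sphere", treated as outside the cavity) are
reliable.  That in turn allows a very large enclosing super-tetrahedron
(insphere radius 1e4 × the data bounding sphere by default): thin hull
elements have circumspheres far larger than the data extent and survive
only if the super-tet vertices are effectively at infinity.  With both in
place, the construction reproduces Qhull's convex-hull volume to machine
precision and passes a brute-force empty-circumsphere audit.  Insertion
order is the input order; the whole pipeline is deterministic.

Constrained meshing takes a closed triangulated surface (every face edge
shared by exactly two faces, validated up front).  Lost constraints are
detected *geometrically*: an edge is present when the mesh vertices lying
on it chain from endpoint to endpoint through mesh edges; a face when the
mesh facets whose vertices lie on it tile its full area — so entities
split by Steiner vertices still count as present.  Recovery first applies
re-diagonalization flips: a missing edge blocked by a coplanar crossing
edge cd is realized by re-splitting *all* fans around cd (both sides of
the quad plane at once — flipping one side only would leave a cracked
interface).  When no flip applies, a Steiner point is inserted on the
offending entity: the midpoint of the missing sub-segment for an edge;
for a face, the point where a piercing mesh edge crosses the face (that
point lies on the face), falling back to the centroid.  Exterior deletion
("dyeing") flood-fills from the super-tet-incident tets, never crossing a
facet contained in a constraint face, and deletes the marked tets and the
super vertices.  On the cube and L-prism fixtures (with and without random
interior points) the result contains every constraint face and matches the
analytic volumes exactly.

Sliver handling: a tet is flagged when its minimum dihedral is below 5° or
volume/(longest edge)³ below 0.01 (both tunable).  Classification follows
the two-category scheme: type 1 when the tet has all four facet-neighbors
and two of them share a common fifth node — then the three tets around the
shared edge are replaced by two (3-2 flip; volume conserved, count −1);
everything else, including boundary slivers with missing neighbors, is
type 2 and treated by relocating one movable (non-boundary) vertex to
maximize the minimum quality ratio over its star (Nelder–Mead), accepting
only strictly improving moves that invert nothing.  The optimization pass
accepts an operation only if the *global* minimum dihedral does not
decrease.  A sliver whose vertices are all on the boundary is reported
unresolved rather than risking the surface.

## Phantoms: what they emulate and what they do not

The tissue phantom is a simulator-style surrogate: nested slightly
elliptical regions for background (mean 10) plus three tissue classes with
means 50/120/200 (CSF-like, gray-matter-like, white-matter-like) on a
128×128 grid; fractional boundary radii (0.42, 0.30, 0.19).  Noise is
additive Gaussian with std = noise% × brightest mean (3% → std 6).  The
bias ("migration"/offset) field is a smooth low-order polynomial rescaled
to span exactly [1 − p/200, 1 + p/200] (40% → [0.8, 1.2]).  Generation is
bit-reproducible from (spec, seed).

What passing on these phantoms shows: correct mechanics of every stage,
robustness to calibrated noise and bias, and the qualitative method
ordering (local-fitting level set ≥ kernelized fuzzy clustering ≥ fuzzy ≥
hard clustering under bias).  What it does not show: performance on real
anatomy — the phantoms have no partial-volume voxels, no anatomical shape
complexity or topology changes, no Rician/structured noise, and class
means far enough apart that intensity alone nearly separates them.
Absolute AOM values here sit near 1.0 and should be read as ceiling
behavior of a correct implementation at these conditions, not as clinical
performance; published overlap figures on real simulated brain data are
necessarily lower.

Metric conventions: AOM is the Dice coefficient; two empty sets score 1
(vacuous agreement).  Overall scores are the arithmetic mean of per-class
AOMs rounded half-up to two decimals.  SNR uses log base 10 (dB).
Unsupervised label maps are matched to ground truth by greedy best overlap
before scoring.

## Known limitations

* The level-set engine is two-phase per run; multi-class output comes from
  per-class runs and arg-max fusion, which cannot represent nested
  contours of the *same* class.
* Boundary recovery handles piecewise-planar surfaces (flips) plus a
  generic Steiner fallback; heavily non-planar constraint intersections
  could demand many Steiner points, and recovery gives up with a clear
  error after a bounded number of rounds.
* Brute-force point location and cavity search are O(n·m); fine for the
  desk-scale meshes targeted here (hundreds of points), not for large
  clouds.
* The ant-colony segmenter composes the walk and assignment behaviors in
  one defensible way (walk pheromone scales assignment reinforcement);
  other couplings are conceivable, and results at these phantom scales are
  driven mostly by the feature heuristic.
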