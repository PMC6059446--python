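# Methods

## Model

The package localizes a 3-D point by regression of voxel-wise unit
directions.  A training sample is S = (v, x, û) with û the unit vector
from voxel x to the target of volume V_v.  A single randomized binary
tree maps any voxel to a small set of clustered directions; inference is
a stochastic walk along those directions.  Axes follow the radiological
convention: X right-to-left, Y posterior-to-anterior, Z
inferior-to-superior; voxel indices are 0-based and physical coordinates
are `index * spacing` in mm.

### Features

The split feature is f_θ(x) = (I(x+v₁) − I(x+v₂)) / I(x).  Dividing by
I(x) makes it invariant to multiplicative intensity changes (contrast
agent dose).  Because stored CT values can be ≤ 0, every volume is
shifted on load by (1 − min) when its minimum is below 1, making every
denominator ≥ 1; the shift is uniform over the volume, so the
contrast-invariance argument is unaffected, and it is recorded in the
volume's provenance label.  All lookups clamp out-of-bounds indices to
the nearest border voxel so walkers probing past the border still see
finite, smooth values (zero-filling would create an artificial edge).

Offsets are drawn componentwise-uniformly from a phase box: |p_x|,|p_y| ≤
80, |p_z| ≤ 40 voxels for the global phase and 40/40/20 for the local
phase at full clinical scale.  The Z bound is half the in-plane bound
because the slice spacing is larger than the in-plane spacing.

### Split search

The threshold τ is not given a fixed scale: for each proposed θ the
feature is evaluated on the node's samples and τ is drawn uniformly
between the empirical 5th and 95th percentiles (order statistics at ranks
`floor(q·(n−1))`).  This guarantees candidate thresholds that actually
partition the node.  Per node, `n_theta` offset pairs × `n_tau`
thresholds are scored (defaults 200 × 10; the desk-scale study uses
40 × 8 globally and 20 × 8 locally); all random draws happen before any
feature evaluation, so the candidate set is a pure function of the RNG
state and can be replayed by an independent oracle.  The objective — the
summed within-child squared deviation of the unit directions, with the
child mean taken arithmetically and *not* re-normalized — is evaluated
for all thresholds of one θ in a single sort + prefix-sum pass.  Ties
keep the first candidate in θ-major order.  A node becomes a leaf when
its mean squared deviation falls below `min_variance` (default 0.05;
deviation of unit vectors is bounded by 4, so this is near-consensus),
when it holds fewer than `min_samples` samples (default 20; 50 in the
desk-scale study), at a safety depth cap (default 25), or when every
candidate leaves a side empty.

### Leaves

Leaf directions are clustered with Lloyd's k-means (k = 8), initialized
by a seeded choice of k distinct samples, at most 50 iterations, empty
clusters dropped.  Final centroids are re-normalized to unit length —
walkers step a fixed distance along them, so their magnitude must be
1 — and a centroid whose mean collapses to ~0 (opposing members) falls
back to the direction of its first member.  Cluster probabilities are
population fractions.  The sample lying exactly on the target voxel has
an undefined direction and is excluded at sample construction.

### Walks

A walker keeps a continuous position accumulator clamped to the volume
box; the rounded integer voxel is used for tree traversal, and the
rounded stepped positions (m ≥ 1; the initial point is excluded) are what
the mean and the walk variance accumulate.  The walk variance is the sum
of per-axis population variances, maintained by a single-pass Welford
update that matches the two-pass definition to 1e−9.  Each walker of a
colony draws its per-step uniforms from its own seeded substream, so
colonies are bit-reproducible and a walker's trajectory is independent of
colony size; variance ties select the lowest walker index.  A colony of
size 1 *is* the RTW baseline — the comparison between the two methods
always consumes byte-identical trees.

### Two-phase pipeline

Phase 1 trains one tree on whole volumes, stride-subsampled (every
coordinate ≡ 0 mod sstep, default 4), targeting a representative valve
point x_g — by default the non-coronary hinge, which all landmarks
surround within ±50 voxels at clinical scale.  Phase-1 error up to 30
voxels is tolerated: the estimate only seeds phase 2.  Phase 2 trains one
tree per landmark on the voxels of a 160 × 160 × 80 cuboid centered on
the landmark (clipped at volume borders; large enough to contain the
phase-1 estimate despite its error).  At desk scale the cuboid covers the
whole phantom; a `stride` parameter (default 1 = every voxel) and a
random `max_samples` cap keep training proportionate.  Phase-2 walkers
start uniformly inside a box of half-extents (10, 10, 5) voxels around
the phase-1 estimate — scattered rather than coincident, so the colony
explores different approach paths; the Z half-extent is smaller to stay
well inside the cuboid's Z half-extent.

## Synthetic phantoms

The generator emulates contrast-enhanced CT of the aortic root, not its
anatomy in detail: piecewise-constant tissue classes (background 60,
vessel wall 140, enhanced lumen 400, less-enhanced outflow tract 280,
commissural ridges 190, calcification 800) plus additive Gaussian noise
(σ = 8).  Geometry at the default 96 × 96 × 72 grid with (1, 1, 1.5) mm
spacing — the Z-anisotropy motif of clinical CCTA at roughly 1/5 clinical
scale: annulus radius 12 voxels (24 mm diameter), commissures 7 voxels
(10.5 mm) and ostia 8 voxels (12 mm) above the annulus plane.  Two
contrast-filled coronary branches leave the root at the right/left sinus
azimuths; together with the three commissural ridges they break all
rotational symmetry, so every landmark is identifiable from intensities.
Rigid pose rotation about X and Y is applied by evaluating the analytic
scene at inverse-rotated coordinates — the exact continuum limit of
inverse-mapped trilinear resampling (no discrete resampling step ever
occurs) — while landmarks are transformed analytically, so ground truth
carries no interpolation error.  Calcification blobs are spheres of
radius 2–4 voxels placed within 1.5 annulus radii of a random hinge.

What the phantom does **not** model: cusp/leaflet meshes, motion and
blooming artifacts, beam hardening, scanner-specific noise spectra, and
anatomical variability beyond rigid pose.  Passing tests therefore
demonstrate correct mechanics and the method's qualitative behaviour
(coarse-to-fine recovery, robustness of the colony to misleading regions,
variance-based selection), not clinical-grade accuracy on real CCTA.

## Desk-scale study configuration

`pipeline.desk_scale_config()` scales the full clinical geometry
(512 × 512 × ~300 voxels) down by the same factor as the phantom grid:
global offsets 15/15/10 and local offsets 8/8/5 voxels, global stride 4,
local stride 3 with a 150 k-sample cap per tree (200 k global), candidate
budgets 40 × 8 / 20 × 8, `min_samples` 50, colony size 200, 64 steps,
step lengths 4 (global) and 2 (local) voxels.  The study cohorts are 30
training phantoms (poses rotated up to ±8° about X and Y, no
calcification), 10 held-out phantoms from the same distribution, and a
stress cohort of 10 phantoms with ±12° rotations and 4 calcification
blobs each — mirroring the train-on-clean / test-on-calcified design of
preoperative TAVI evaluation.

## Numerical choices

- Feature matrices are computed in float32 (volumes are float32); split
  objectives and all direction arithmetic use float64 prefix sums.
- `rint` half-to-even rounding maps continuous walker positions to
  voxels.
- The circumcircle uses the closed form d = abc/(2·area) with the
  circumcenter in barycentric coordinates; collinear hinges (area ~ 0)
  are rejected.  Plane normals are canonicalized to positive Z (then Y,
  then X), and the view-plane cosine distance is 1 − |n₁·n₂|, since a
  plane is unchanged by flipping its normal.
- The paired method comparison uses the Wilcoxon signed-rank test on
  per-volume mean errors (robust to the skewed error distributions of
  localization tasks); a paired t-test is available as an option.
  Identical arms make the statistic degenerate and are reported as NA.

## Known limitations

- At desk scale the learned direction field has a volume-specific fixed
  point offset of 1–3 voxels (pose-generalization error of a single tree
  trained across ±8° rotations); it dominates the converged error and is
  not reduced by finer leaves.  Consequently walk variance discriminates
  converged from misled walks very well, but carries little information
  *within* the converged population.
- Single trees only (no forests), integer-voxel stepping in index space
  (anisotropy is inherited from spacing), and no multi-threading: the
  implementation favours auditability over speed.
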