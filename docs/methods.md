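# Methods

`mandifem` implements the full analysis chain used to compare chewing
biomechanics and mandible shape across a clade and to assign unlabeled
specimens to broad ingesta-hardness categories.  This note documents the
models, the numerical choices, and what the synthetic data do and do not
emulate.

## Plane-stress finite-element model

A mandible in lateral view is treated as a thin plate loaded in its own
plane (plane stress): two dimensions are much larger than the thickness,
so through-thickness stresses are neglected.  Each model has a single
constant thickness, the mean of three corpus breadth measurements, and
isotropic, homogeneous, linear-elastic cortical bone properties
(defaults E = 21 GPa, stored as 21000 MPa, and nu = 0.45; units are
fixed as mm / N / MPa throughout).  Absolute property values matter
little in a comparative analysis; what matters is that all specimens
share them.

Elements are 8-node serendipity quadrilaterals (QUAD8) with straight
sides (mid-side nodes at geometric edge midpoints; boundary curvature is
captured by boundary resolution rather than curved element edges).
Stiffness and stress recovery use 2x2 Gauss quadrature, the standard
reduced scheme for this element and the common commercial-solver
behaviour; full 3x3 integration is available (`order=3`) and is used in
tests to confirm the element has exactly three zero-energy (rigid-body)
modes.  The single element-level hourglass mode of the reduced scheme is
not communicable in a connected mesh.  The assembled system is solved by
sparse LU after constraint elimination (problem sizes stay below ~10^5
dof).  Non-zero prescribed displacements are supported, which the
constant-strain patch test uses.

Because the area-weighted percentile statistic needs one stress value
per element, the von Mises stress `sqrt(sx^2 + sy^2 - sx sy + 3 txy^2)`
is evaluated at each Gauss point and averaged over the element with
Gauss-weight x |J| weighting.  Averaging the invariant (rather than
averaging components first) was chosen because it is the quantity the
percentiles summarise; for the patch test both give the exact constant.

Verified properties: the distorted-patch constant-strain test is exact
to machine precision; a uniaxially loaded strip reproduces
sigma_vm = F/(w t) to 1e-6; cantilever tip deflection converges
monotonically and sits within 3% of Euler-Bernoulli at ~2000 elements
(the converged value exceeds beam theory by the expected shear
contribution); solutions are invariant under rigid rotation of model
plus loads.

## Quasi-uniform quadrilateral meshing

Element-wise stress statistics are biased when element sizes vary, so
meshes aim for near-uniform element area ("quasi-ideal"): the sample
coefficient of variation of element areas is typically 0.15-0.25.  The
mesher triangulates the outline (uniform arc-length boundary sampling
refined adaptively where the outline curves, a jittered hexagonal
interior lattice, Delaunay, inside-filtering) and then splits every
triangle into three quadrilaterals through its edge midpoints and
centroid.  This midpoint subdivision guarantees an all-quad mesh on
arbitrary simple polygons — including strongly concave ones such as the
mandibular notch — and each quad receives exactly one third of its
triangle's area, so area uniformity is inherited from the triangulation.
Quality-guarded ("smart") Laplacian smoothing is applied at both the
triangle and quad stages: a node moves only if the worst incident
element's quality does not degrade, which is robust near concave
boundaries where plain Laplacian smoothing drags nodes outward.  Rare
pathological boundary triangulations are handled by a deterministic
retry ladder over slightly perturbed spacings.  Boundary midpoints are
projected back onto the true outline, keeping the meshed area within 1%
of the outline polygon's area and boundary nodes within a tenth of the
element size of the outline.  Axis-aligned rectangles take a structured
transfinite path (used by the solver benchmarks).

The pipeline default element size (0.65 mm on the default ~60 mm
mandible) yields roughly 5000 elements per specimen, enough that halving
the element size changes the median stress percentile by well under 2%.
Tests and the acceptance script run at 2.0 mm (~500 elements), which the
same convergence check shows is already within a few percent for the
percentile statistics; the methods' conclusions do not change between
these densities.

## Bite scenarios, muscle forces, force scaling

Models are oriented with the occlusal plane along +x and the anterior
end at +x.  Four load cases differ only in the bite point: incisive
(IB), canine (CB), premolar (PB, at the distal premolar / M1 boundary)
and molar (MB, centre of M1).  The condyle node (most posterior condyle
landmark) is fixed in both directions, standing in for the contact with
the mandibular fossa; the bite node is fixed only perpendicular to the
occlusal plane, generating the bite reaction.  These constraint
directions remove all rigid-body modes; the solver refuses
under-constrained cases naming the free mode.

The total muscle force is split between masseter, temporalis and medial
pterygoid in proportion to their relative attachment areas (generator
defaults 0.50 / 0.375 / 0.125, summing to 1).  Each muscle's share is
divided equally across the mesh boundary nodes of its insertion arc
(per-node equal shares; the arcs are narrow enough that area weighting
within an arc is indistinguishable), all pointing from the insertion-arc
centroid toward the muscle's origin centroid.

Specimens of different size are compared by scaling the total force
quasi-homothetically against a reference specimen carrying exactly 1 N:
`F = sqrt(S / S_ref) * (t / t_ref)` with S the lateral outline area and
t the thickness.  Nominal stress goes as F/(length x thickness), so this
choice makes the stress field of a geometrically similar model
independent of its absolute size — verified end to end: scaling an
outline by 2 and thickness by 2 reproduces the element von Mises field
exactly (the check is algebraic for a linear solver, and the test
confirms the whole load-construction path preserves it).

## Area-weighted stress percentiles and PERMANOVA

Each solved scenario is summarised by the 25th, 50th, 75th and 95th
percentiles (M25-M95) of element von Mises stress on the area-weighted
empirical distribution: the percentile is the smallest element value
whose cumulative normalised element-area weight reaches p/100 (a step
ECDF / weighted lower quantile, not interpolated — well-defined for any
weights and verified against a brute-force weight-expansion oracle).
The maximum stress is deliberately not modelled; peak values behave
similarly across diet classes and are dominated by the constraint
singularities.  Four scenarios x four percentiles give 16 variables per
specimen.

Group differences use one-way PERMANOVA on Euclidean distances:
Anderson's pseudo-F from the partition of the total sum of squared
distances into among- and within-group parts, with
`p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)` over label permutations
(default 9999) and a step-down Holm correction across group pairs.  The
permutation test is exact by construction; simulation confirms a type-I
error of 0.05 at alpha = 0.05 and agreement with exhaustive enumeration
at n = 4 + 4.

## Shape analysis and phylogenetic statistics

Twelve fixed landmarks per mandible (alveolar points at the four bite
positions, gnathion, posterior alveolar point, coronoid tip, deepest
mandibular notch, posterior condyle, posterior ramus midpoint, gonion,
corpus base midpoint) are superimposed by generalized Procrustes
analysis: centre, scale to unit centroid size, and iteratively rotate
(rotation only, no reflection) to the running consensus until the
consensus moves by less than 1e-10.  Aligned coordinates are not
projected to tangent space by default (shape variation here is small; a
projection flag exists).  PCA is the eigendecomposition of the
covariance of the flattened aligned coordinates.

Phylogenetic statistics assume Brownian motion, encoded in the
phylogenetic covariance matrix C of shared root-to-MRCA branch lengths:

* **Kmult** — the multivariate K statistic: the ratio of the
  mean-centred to the C^-1-weighted (GLS) residual sum of squares,
  divided by its BM expectation `(tr C - n / (1' C^-1 1)) / (n - 1)`.
  K = 1 in expectation under BM on the tree, smaller when phylogeny
  explains less of the covariation.  Significance permutes specimen rows
  across tips (default 999 permutations).
* **Phylogenetic PLS** — both blocks are GLS mean-centred and
  premultiplied by C^(-1/2) (symmetric eigendecomposition with an
  eigenvalue floor of 1e-12 for near-ultrametric trees); the first
  singular-vector pair of the cross-block covariance gives scores whose
  correlation is r_PLS, tested by permuting rows of one transformed
  block (default 9999 permutations).

On a star phylogeny both reduce to their non-phylogenetic counterparts
(tested).  Calibration: mean K over 200 BM simulations on a 30-tip tree
lies in [0.9, 1.1]; null PLS permutation p-values are uniform.  The
univariate special case of K is cross-checked against an independent R
implementation.

## Diet classification

Two linear-kernel SVMs separate hard- from soft-food eaters: one on the
16 stress percentiles, one on the leading shape PCs (the smallest set
reaching 95% cumulative variance).  Stress percentiles are Box-Cox
transformed per variable (lambda maximising the profile likelihood on
[-5, 5]) and standardised to zero mean / unit sd; PC scores need no
preprocessing.  The cost parameter is tuned by leave-one-out
cross-validation over an automatic grid (2^-5..2^7) followed by a manual
refinement of ten values within +-50% of the best, ties resolved toward
the smaller (more regularised) cost.  All preprocessing is refit inside
every fold, so nothing leaks from the held-out specimen; the reported
accuracy and Cohen's Kappa are the pooled LOOCV estimates at the
selected cost.  Note that selecting the cost by the same LOOCV estimate
that is reported gives the usual mild optimism under the null; the null
behaviour is still within binomial noise of 0.5 in tests.  Class
probabilities come from a Platt sigmoid fitted (with Platt's smoothed
targets) on the cross-validated decision values; unlabeled specimens
never enter training and are assigned P(hard)/P(soft) through the
full-data preprocessing and model.  The hard class is the positive
class.  An unlabeled specimen's overall call combines the two models by
averaging their posteriors, mirroring an analysis that weighs
biomechanical and morphometric evidence equally.

## What the synthetic data emulate — and what they do not

The generator stands in for a photograph-derived comparative sample: a
pure-birth (Yule) phylogeny rescaled to unit height; eight interpretable
outline parameters (corpus length/height, ramus and coronoid heights,
gonial angle, condyle offset, symphysis depth, base thickness) evolving
as independent Brownian motions on the log scale (so lengths stay
positive) with relative tip sd 0.08 (0.04 for the angle) at
`sigma_bm = 1` — roughly the coefficient of variation of linear
mandible dimensions across a primate-like clade; a smooth periodic-
spline outline through ~19 anchor points with the 12 landmarks among
them; a balanced binary diet split where hard eaters get
`diet_effect` tip-sd of extra log corpus height and thickness
(`diet_effect = 3` gives the clear-but-imperfect class separation real
hard/soft comparisons show); fossils as pendant tips grafted at random
tree points, generated from the soft regime by default and never
labeled; and i.i.d. Gaussian landmark/measurement noise (default
0.1 mm, a typical digitisation error).

Because the diet offset raises corpus height, it changes *shape* and
hence scaled stress — thickness alone would not, since the
quasi-homothetic force scaling cancels uniform thickness.  Group
separation measured in pooled cross-tip standard deviations slightly
exceeds `diet_effect` because tips are phylogenetically correlated,
which shrinks the pooled sd below the marginal tip sd; tests therefore
calibrate against the marginal sd.

Not emulated: within-species variation, allometric shape-size trends,
non-Brownian evolution (selection regimes, rate shifts), muscle
architecture differences between diets, cortical/trabecular
heterogeneity, and digitisation artifacts beyond white noise.  Passing
tests therefore show that the chain recovers the signals it assumes —
not that those assumptions hold for any particular real clade.
Gonial-angle draws are clipped to [95, 150] degrees to keep outlines
anatomically shaped; at the default rates clipping is a < 1e-3
probability event and does not measurably distort the BM calibration.

## Degenerate inputs and tie-breaks

Non-simple outlines, non-positive Jacobians and unmeshable geometries
raise `GeometryError`; insertion arcs or bite landmarks that miss the
mesh raise `MappingError` (a bite landmark must lie within one element
size of a boundary node); under-constrained load cases raise
`SolverError` naming the free rigid-body mode; degenerate (coincident)
landmark configurations are rejected naming the specimen.  Percentile
ties resolve to the smallest qualifying value (stable sort); SVM cost
ties resolve to the smallest cost; Kappa with degenerate margins is
defined as 0 with a warning.  All stochastic stages consume
`numpy.random.default_rng` seeds derived from one pipeline seed and
logged, making every output reproducible bit for bit.
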