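# Methods

This note documents the models, numerical choices and limitations behind
`callimorph`, a pipeline for phylogenetically informed 3D geometric
morphometrics of limb long bones (the motivating system is the callitrichid
humerus/femur dataset contrasting vertical clinging and leaping, VCL, with
horizontal leaping, HL).

## Shape representation and superimposition

A specimen is a k x 3 landmark configuration in mm, each point carrying a
role: fixed anatomical landmark, ordered point on a named curve, or surface
semilandmark. Centroid size (CS) is the square root of the summed squared
distances of the landmarks from their centroid.

Superimposition is *full* generalized Procrustes analysis: configurations
are centred, scaled to unit centroid size and rotated to an iteratively
updated consensus until the consensus moves by less than 1e-10 (max 100
iterations). Only proper rotations are used — reflections are forbidden
everywhere so left/right bones can never be mirrored implicitly; side
handling is the caller's responsibility. No bilateral-symmetry correction is
applied. The species mean form is the species-level Procrustes consensus
rescaled by the arithmetic mean of the specimens' raw centroid sizes.

Duplicate digitizations of one specimen are combined by rigidly aligning
the second onto the first (no scaling) and averaging pointwise — the
minimal-variance combination of replicate measurements.

## Thin-plate splines and bending energy

The 3D TPS kernel is phi(r) = r. The interpolant solves the bordered system
[[K, P], [P', 0]] with K_ij = |x_i - x_j| and P = [1 | X]. Because |r| is
conditionally negative definite of order 1, the landmark block of the
inverse bordered system is negative semidefinite; the bending-energy matrix
is defined as MINUS that block, making it PSD with the affine maps of the
reference as its null space. Eigenvalues in [-1e-10, 0) are clipped to zero.
Bending energy of a target is the quadratic form summed over the three
coordinate axes.

## Semilandmark processing

Curves are resampled to equal arc-length spacing along the piecewise-linear
digitized polyline, endpoints preserved exactly. Surface semilandmarks are
transferred from a template (one designated specimen carrying the full point
set) by TPS-warping through the fixed+curve scaffold and projecting each
warped point to the closest point on the specimen mesh.

Sliding minimizes bending energy against a reference (first the template,
then the sample consensus for three iterations). The reference is first
aligned onto the specimen by scaled ordinary Procrustes; the sliding
amplitudes then solve the generalized-least-squares problem
t* = -(U'BU)^+ U'B(y - x) in closed form, where U stacks the per-landmark
tangent bases and B is the 3-axis block-diagonal bending-energy form. The
pseudo-inverse (minimum-norm) solve is used because tangential motions that
are nearly affine make U'BU nearly singular. Tangent bases: a curve point
slides along the normalized chord between its neighbours (one-sided at curve
ends); a surface point slides in the plane orthogonal to the local mesh
normal, taken from the nearest mesh *vertex* (face normals are tie-ambiguous
exactly at vertices, where semilandmarks usually sit). The in-plane basis is
anchored to the configuration's own geometry so the whole sliding step is
rigid-motion equivariant. After every slide, curve points are re-projected
onto the specimen's digitized curve and surface points onto the specimen
mesh (slide-then-project, never deferred); fixed landmarks never move. Both
curve and surface points slide by default; curve sliding can be disabled.

Point-to-mesh projection is an exact brute-force point-triangle query
vectorized over all faces; the meshes used here are ~2k faces, for which
this is faster than building spatial indices.

## Trees and the composite phylogeny

Trees are rooted, strictly bifurcating (polytomies raise an error rather
than being silently resolved; an explicit opt-in exists for analytic special
cases such as the star phylogeny), with branch lengths in My. Taxa are added
to a backbone from patch phylogenies by cross multiplication: for a new
taxon X sharing species S with the backbone, the scaling factor is
f = depth(S, backbone) / depth(S, patch) and X attaches to S's lineage
f * t_div My before present with a pendant of the same length, where t_div
is the X–S divergence in the patch. If that time falls beyond an internal
node the attachment climbs to the next ancestral edge. Grafting preserves
ultrametricity when both inputs are ultrametric.

The repository encodes the study system's 25-tip topology as a fixture with
APPROXIMATE round-number branch lengths; only topology-dependent results
(parsimony ancestral states) are asserted against it.

## Ancestral states

Parsimony uses unit costs with a Sankoff up-down pass; each node's
probability vector is uniform over the states occurring in at least one
most-parsimonious reconstruction at that node. Stochastic character mapping
uses the 2-state equal-rates Markov model with the rate fitted by maximum
likelihood (pruning algorithm, bounded search on log rate) and a flat
(0.5, 0.5) root prior. Node states are sampled jointly (root from its
conditional posterior, then each child given its parent); within-branch
histories are sampled by uniformization, which for the 2-state equal-rates
chain reduces to a parity-constrained Poisson number of change points.
Invariant tip data short-circuit to rate 0 and certainty at every node.

## Phylogenetic signal, ANOVA, MANCOVA

Blomberg's K uses the Brownian covariance C of shared root-path lengths and
the GLS phylogenetic mean; the multivariate Kmult shares the same ratio
structure over summed coordinates and reduces exactly to K in one dimension.
Both are permutation-tested by shuffling values across tips. Phylogenetic
ANOVA takes the standard one-way F but draws its null distribution from
Brownian simulations on the tree with sigma^2 estimated from the data by the
GLS residual estimator. All permutation/simulation p-values use the add-one
rule (#extreme + 1)/(N + 1), so they lie in (0, 1] and never vanish.

Shape dimensionality is reduced to the smallest leading set of PC axes
reaching 95% cumulative variance (capped so the MANCOVA retains at least
four residual degrees of freedom). The MANCOVA is the sequential (Type I)
multivariate linear model scores ~ size + locomotion + size:locomotion with
Pillai's trace per term and Rao's F approximation, error SSCP from the full
model — the printed row order (size, locomotion, interaction) is the fitting
order. Only two locomotor groups exist, so the omnibus test is its own
post-hoc and no pairwise correction is applied.

## Ordination and classification

PCA uses a deterministic sign convention (largest-magnitude loading
positive). The phylomorphospace projects internal nodes at their per-axis
GLS Brownian ancestral estimates and exports parent-child edges.
Between-group PCA diagonalizes the covariance of the (equally weighted)
group mean vectors; with two groups there is exactly one axis, collinear
with the difference of group means. By default the classifier operates in
the PC-reduced (95%) space; full shape space is available by flag.

Typicality classification converts the squared Mahalanobis distance to each
group centroid (pooled within-group covariance) into a probability through
the small-sample F transformation; assignment is argmax, with specimens
whose best typicality falls below 0.05 flagged "atypical" but still
assigned. Under cross-validation the evaluated specimen is excluded from
its group mean, the pooled covariance, *and* the bgPCA axes themselves —
leaving the axes fixed leaks the labels through the projection (the known
bgPCA overfitting artifact) and produces above-chance accuracy on random
labels, which the test suite checks explicitly. Group separation is tested
by permuting group labels and comparing the Euclidean distance between
group means (one-tailed: only large distances indicate separation).

## Branch rates and shift detection

Phylogenetic ridge regression writes each tip phenotype as the GLS root
estimate plus branch-length-weighted contributions of the branches on its
root path; rates are beta = (X'X + lambda I)^-1 X'(Y - root) per dimension,
and a branch's rate magnitude is the Euclidean norm of its rate vector.
When lambda is not supplied it is tuned by golden-section search on
log-lambda over [1e-8, 1e4] (times the mean diagonal of X'X) minimizing
leave-one-out tip prediction error computed through the ridge hat matrix.
The reference method's exact penalty-tuning criterion is not public
documentation; this choice is validated by calibration (planted-shift
recovery and null false-positive rates) rather than numerical equivalence.

Shift search compares, for every clade with between 2 and n/2 tips, the
mean rate magnitude of the clade's branches (stem included) with the mean
over all other branches; the null shuffles branch magnitudes globally, the
p-value is two-tailed with the add-one rule, and directions (higher/lower)
are flagged at alpha = 0.05. Raw per-clade p-values are reported, as in the
motivating analysis; a Benjamini-Hochberg column is appended for reference.
Nested significant clades are reported independently (no winnowing).

## Synthetic data generator

The generator emulates the study design with known ground truth: a
bone-like template (cylindrical shaft, two bulbous epiphyses; watertight
mesh of ~1000 vertices) carrying fixed landmarks at analytic feature
points, ridge curves, and surface semilandmarks on exact mesh vertices;
species mean shapes evolving by multivariate Brownian motion in the tangent
space at the (unit-centroid-size) template, with optional clade rate
multipliers and an additive VCL group offset; specimens realized per
species with an allometric deformation proportional to drawn log centroid
size, isotropic landmark noise, a TPS-warped copy of the template mesh, and
a random rigid motion. Defaults: the 25-tip fixture tree, up to three
specimens per species (as in the motivating sample), base rate sigma^2 =
1e-4 Procrustes-units^2/My (giving root-to-tip shape displacements of a few
percent of size, typical of congeneric skeletal variation), group offset
0.02 and allometry 0.03 Procrustes units, digitization noise 0.004
(≈0.4% of size), log sizes in [3.4, 4.0] log-mm (≈30–55 mm bones).
Regeneration from the same recipe and seed is bit-identical.

What the generator does *not* emulate: real bone geometry beyond the
landmark-role structure, digitizer-specific error anisotropy, missing data,
measurement batch effects, or non-Brownian evolutionary processes
(selection regimes, early bursts). Passing calibration tests therefore
demonstrates statistical correctness of the machinery under the stated
model, not robustness to violations of it.

## Pipeline, seeds, determinism

The pipeline executes resample → patch → slide (3 iterations) → GPA →
species means → size statistics (Welch t-test + phylogenetic ANOVA) →
signal (K, Kmult) → MANCOVA → bgPCA (+classification, permutation test) →
phylomorphospace → ridge rates → shift search → ancestral states, with
per-stage toggles. Defaults follow the study settings: 3 sliding
iterations, 95% PC variance, 10,000 permutations, 1000 simulations. Every
stochastic stage derives its own seed deterministically from the config
seed, output files carry the config echo in commented headers, and the log
format omits timestamps, so a rerun with the same config and seed is
byte-identical — asserted by the test suite.

## Problem sizes used by the test and acceptance suites

Calibration experiments run at sizes chosen to give stable Monte-Carlo
estimates with desk-scale runtimes: 500 Brownian replicates for K/Kmult
calibration on a 25-tip tree; 500 replicates with 1000 Brownian simulations
each for the phylogenetic-ANOVA calibration on a 16-tip two-clade tree; 200
replicates with 1000 randomizations each for planted-shift power (8x rate
multiplier in a 6-tip clade of 30 tips) and for the null false-positive
rate; 200 replicates for classifier chance-level and permutation-uniformity
checks. End-to-end pipeline checks use 8–10 species with 1–2 specimens
each and the default template (6 fixed, 8 curve, 24 surface points).

## Known limitations

- The composite-phylogeny scaling rule follows the cross-multiplication
  description exactly; where a scaled divergence falls inside an internal
  edge near a speciation node the attachment rule (attach on the lineage's
  edge at the scaled time, climbing if necessary) is a documented choice.
- The ridge-penalty tuning criterion and the handling of nested significant
  clades are this package's documented choices, validated by calibration.
- Sliding monotonicity of total bending energy is guaranteed only before
  re-projection; projection displacements are second-order for the small
  tangential corrections the tests exercise, and the monotonicity assertion
  carries a matching tolerance.
- The simmap root posterior on the real system depends on true branch
  lengths, which the fixture tree only approximates; it is exposed but not
  asserted against published values.
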