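# Methods

This note records the models, conventions and numerical choices behind
`osteomorph`, and what the synthetic-data tests do and do not
demonstrate about real CT data.

## Volumes, axes and ROIs

All operations act on isotropic voxel grids (`VoxelVolume`) with the
physical edge length in μm; anisotropic input is rejected. Axis 0 is
the proximodistal axis after reorientation, slice 0 the most proximal
slice. Reorientation aligns the dominant principal axis of the bone
mask's voxel-coordinate covariance with axis 0 by a rigid rotation
(Rodrigues construction), resampling nearest-neighbour for binary
volumes (preserving binarity) and trilinearly for greyscale
(preserving smoothness); the applied rotation matrix and angle are
recorded in the output metadata. A mask whose two leading covariance
eigenvalues differ by less than 5% (relative) has no well-defined long
axis; the input is returned unrotated with a warning.

Percent-length ROI addressing uses `floor(fraction × total_slices)`
with half-open intervals `[begin, begin + extent)`. The literature
rarely states whether such sites are inclusive or exclusive of the
reference slice; this convention is a package choice and is written
into the ROI metadata of every output. Anatomical reference slices
(trabecular bridge, tibia–fibula junction, condyle slice) are user
inputs — landmark detection is out of scope — and the fibula is removed
by a user-supplied mask, not computed.

## Segmentation and digital topology

Global thresholding uses `intensity ≥ t`, with Otsu's between-class
variance criterion as the automatic option. Despeckling removes
connected components of one phase strictly smaller than a voxel count
(idempotent by construction); the defaults exposed in the CLI are one
pass of foreground min-size 5 then background min-size 5, and whatever
is used is recorded in the run config, because the equivalent settings
in commercial CT suites are typically unreported. The synthetic presets
skip despeckling (min-size 1) so that planted single-voxel speckle
remains observable as the classifier's noise class.

Foreground (bone, pores-as-objects) uses 26-connectivity and the
complement 6-connectivity — the standard dual pair that avoids
connectivity paradoxes. Component labels are assigned in raster order
of first voxels, so particle decompositions are deterministic.

Pore extraction partitions the complement of the cortical slab into
6-connected components: components reaching the in-plane outer faces
are exterior; components spanning both axial end faces are the marrow
cavity (the slab's axial ends are open); components touching exactly
one axial face are pores censored by the analysis window — excluded
from statistics and counted in `n_excluded`. What remains is enclosed
intracortical void. A pore that breaches the endosteal surface joins
the marrow component and drops out automatically.

## Pore classification and porosity indices

Classification is by physical particle volume (voxel count × voxel
volume), making the rule voxel-size independent: volumes below
13 μm³ are noise, above 1500 μm³ vascular canals, and the inclusive
band [13, 1500] μm³ osteocyte lacunae ("smaller than"/"larger than"
read strictly, so both bounds classify as lacunae).

Ct.TV is the cortical *tissue* volume — bone plus the enclosed pore
space of both classes. Mean per-particle volumes (Lc.V, Ca.V) are
arithmetic means (per-particle distributions are exported alongside);
volume fractions are total class volume over Ct.TV. Class thickness is
the mean sphere-fitting local thickness of the class mask; separation
is the local thickness of the non-pore tissue (tissue minus the class
mask) — the restriction to the cortex mask rather than the bounding
window is a package choice recorded here. Connectivity density is
(1 − χ)/Ct.TV with χ the 3D Euler characteristic of the class mask
(26-connectivity octant counting, via scikit-image); for N disjoint
simply-connected pores this is (1 − N)/Ct.TV, which is negative — the
sign carries the information.

## Best-fit ellipsoids and shape descriptors

Each particle's central second-moment matrix (per unit mass, μm²)
includes the voxel self-moment `voxel²/12·I`, which keeps the matrix
positive definite and measurably improves small-particle accuracy.
Semi-axes come from the uniform-*solid*-ellipsoid relation
λᵢ = √((5/2)(mⱼ + mₖ − mᵢ)) on the inertia eigenvalues — lacunae are
filled voids, matching the solid-body convention of standard particle
analysis tools; a non-positive radicand flags a shape no solid
ellipsoid can produce and the particle is excluded from shape
statistics. Particles under 10 voxels are skipped with a warning:
their moments are discretisation-dominated.

Equancy λ3/λ1, elongation 1 − λ2/λ1 and flatness 1 − λ3/λ2 satisfy
Eq = (1−El)(1−Fl) identically. Flinn coordinates are the raw axis
ratios (x = λ2/λ3, y = λ1/λ2); note that some published Flinn-diagram
captions label these ratios "flatness"/"elongation" even though they
are not the 1−ratio descriptors — both quantities are therefore
exported under distinct names and never conflated. Group summaries
weight particles equally (per-lacuna averages), not by volume.

Accuracy: rasterized ellipsoids with semi-axes down to 3 voxels are
recovered within 5% per axis. Rotation invariance of the shape metrics
is exact in the continuum but limited by rasterization at small radii:
at a 5-voxel minor axis the metric drift under rotation can reach
~2%, so invariance is asserted on well-resolved particles
(minor axis ≥ 7 voxels, drift ≤ 2%).

## Slice geometry, thickness, anisotropy, TMD

Second moments of area are computed about principal centroidal axes
(eigen-decomposition of the 2×2 area-moment tensor) with the 1/12
voxel self-moment — "minor/major axis" always means principal axes.
The polar moment is their sum; over a slab it is reported as the mean
of per-slice polar moments. Total porosity per section uses the
cortical envelope: the filled periosteal contour minus the marrow
cavity, with the marrow identified as the largest enclosed void of the
section (adequate for diaphyseal cross-sections, where the medullary
cavity dwarfs any intracortical pore; it would misidentify a pathology
whose pores rival the marrow). Profile stations sample the nearest
slice at 1% steps with no averaging window.

Local thickness is the Hildebrand–Rüegsegger sphere-fitting
definition: the value at a point is the diameter of the largest fully
inscribed sphere containing it. The implementation takes the Euclidean
distance transform and propagates spheres in descending half-voxel
radius bins, resolving each bin's coverage with one distance
transform; the result is exact to within one bin and costs one EDT per
bin rather than per voxel. Note the discrete convention: a digitized
ball of radius r spans 2r + 1 voxels, so thickness of small spheres
reads one voxel above the nominal diameter; oracles use structures
≥ 12 voxels across where this bias is within the stated ±1 voxel /
±10% tolerances.

Degree of anisotropy uses the mean-intercept-length (MIL) ellipsoid:
128 quasi-uniform Fibonacci-hemisphere directions, 64 parallel test
lines per direction with seeded random offsets, 0.5-voxel sampling
steps; MIL(n) = bone length / intercept count, the tensor H is fitted
by least squares to nᵀHn = 1/MIL², and DA = 1 − MIL_min/MIL_max from
the ellipsoid's principal values. Isotropic media measure ≤ 0.15,
parallel plates ≥ 0.5. Deterministic under a fixed seed.

TMD calibration is the exact affine line through the two
hydroxyapatite phantom points (0.25, 0.75 g/cm³ by default), applied
to the mean attenuation of bone voxels in the analysed ROI (the
conventional 100-slice stack at 37% of length). Equal or inverted
attenuations are rejected.

## Trabecular indices

TV is the user-supplied envelope volume, BV the bone volume; Tb.Th and
Tb.Sp are local thickness of bone and marrow phases. Tb.N uses the
model-independent form (BV/TV)/Tb.Th, since plate/rod model formulas
differ between tools; the choice is recorded in output metadata. χ is
computed without edge correction at the open slab faces (the slab
convention slightly biases Conn.Dn where structures exit the volume).

## Statistics

Each response is fitted by OLS as genotype + age + genotype:age with
age categorical — cohort ages are discrete groups of different
animals, not a longitudinal covariate. Main effects use Type-II sums
of squares, the conventional choice for mildly unbalanced layouts
(e.g. 5 animals in the oldest cell versus 6 elsewhere) absent ordered
interaction hypotheses; the interaction is the full-model term.
Residual normality is assessed per fit by Shapiro–Wilk, and positional
analyses report the median Shapiro p across stations per response.
Post-hoc genotype contrasts within age use Welch's unequal-variance t,
with Bonferroni (×k, capped at 1) for single-site panels and no
adjustment along the 10–90% profile, preserving the station-wise
inferential scale. Significance bands: red p ≤ 0.001, yellow ≤ 0.01,
green ≤ 0.05 (0.05 itself is green), blue > 0.05; the level is fixed
at 5%.

A vectorised permutation test for the interaction (free permutation of
responses, exchangeable under the global null; extra-sum-of-squares F;
add-one correction) serves as an internal cross-check of the
parametric p-values: on a 24-observation table the two agree to ~1e-3
at 10⁵ permutations.

Calibration, measured by simulation: per-effect type-I error is
0.05 ± 0.01 over 2000 null replicates of the default cohort (2
genotypes × 4 ages × 6), and a ±2σ product-pattern interaction at
n = 6/cell is detected with power ≈ 1 (the bound asserted is ≥ 0.80
over 500 replicates). Under the null, ~95% of station bands per effect
are blue; note that requiring *both* the genotype and interaction rows
blue at a station succeeds only ~90% of the time (0.95² jointly), so
the pipeline test asserts the per-effect blue fraction ≥ 0.90.

## Synthetic data: what it emulates and what it does not

Generators rasterize analytic solids by center-of-voxel inclusion (a
voxel is solid iff its center is inside), giving unbiased, analytically
checkable volumes (≤ 5% error for solids ≥ 8 voxels across, improving
with resolution). Defaults mirror the two imaging scales of murine
tibial work: 5 μm voxels (whole-bone microCT) and 0.6 μm (nanoCT of
the lacunar-canal network), so the physical 13/1500 μm³ thresholds are
exercised at realistic scale.

The porous-shell preset plants, per specimen, 50 tri-axial lacunae
(λ3 1.5–2.8 μm, λ2/λ3 1.3–2.2, λ1/λ2 1.2–2.5, long axis near-axial —
volumes ≈ 50–800 μm³, typical of murine osteocyte lacunae and safely
inside the class window so rasterization cannot flip a class), 4
near-axial vascular canals of radius 3.5–4.5 μm with analytic volume
≥ 2200 μm³, and 15 single-voxel specks, placed by rejection sampling
with a 2-voxel clearance inside an 18 μm cortical wall. The clearance
guarantees the labeling stage sees exactly the planted component
count. The cohort simulator draws y = μ + g·[KO] + a_j + d_j·[KO] + ε
with ε ~ N(0, σ²), defaulting to ages 5, 7, 16, 34 weeks and 6
animals per cell (5 at 34 weeks), reproducibly under a seed.

Not emulated: X-ray physics (beam hardening, ring artefacts,
partial-volume blur beyond optional Gaussian noise), canaliculi,
osteonal microstructure, true endocortical contours, or spatially
correlated pore placement. Passing tests therefore demonstrate the
correctness of the measurement chain on geometrically ideal input —
they do not validate segmentation robustness against scanner noise,
which on real data remains governed by the threshold and despeckle
settings recorded in the run config.

## Problem sizes and determinism

Test and acceptance runs use shells of 160 × 111 × 111 voxels with
~70 pores (20 seeds for class fidelity), a 3³-cell trabecular lattice
at 5 μm voxels, 1000–2000-replicate null simulations, 500-replicate
power runs, and 10⁵ permutations — sizes chosen so the full suite
completes in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted tolerances. Every stochastic component takes an
explicit seed; pipeline runs embed the package version, a hash of the
scientific configuration, and the seed in each output CSV, and
re-running an identical configuration reproduces outputs byte for
byte.
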