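# Methods

This note documents the models, conventions and numerical choices behind
bridgekit, and what the synthetic phantoms do and do not establish about
real data.

## Geometry conventions

All grids use axis order (z, y, x); world coordinates are µm in the same
component order. Voxel indices are 0-based and refer to voxel centers:
world(i, j, k) = origin + (i, j, k)·spacing. mm-based formats (NIfTI headers
declaring mm, Slicer FCSV markups) are converted to µm at the I/O boundary;
FCSV RAS coordinates keep their signs and are axis-reversed to (z, y, x).
Orientation differences between scanner frames and window-parallel frames
are never inferred from headers — reslicing is an explicit, logged rigid
transform returned by `reslice_to_plane`.

## Registration

Rigid and similarity fits use the closed-form least-squares orthogonal
(Kabsch/Umeyama) solution with determinant correction; affine fits use
linear least squares. Degenerate landmark configurations are detected from
the singular values of the centered fixed points and reported by name
(coincident / collinear / coplanar).

The elastic mode is a thin-plate spline with kernel U(r) = r in 3D and
U(r) = r² log r in 2D, solved from the standard bordered system with an
optional Tikhonov term λ on the kernel diagonal. λ defaults to 0 (exact
interpolation at the landmarks, residual < 1e-6 µm); a positive λ is exposed
for noisy landmark clicks, and the choice of exact interpolation as the
default is an assumption, not a claim about any particular prior study.

All transforms are fitted in the pull-back direction (fixed/target frame →
moving frame) because resampling evaluates the moving image at transformed
target coordinates. The inverse of an elastic map is obtained by refitting
with landmark roles swapped — exact at the landmarks, with no numerical
field inversion. Composition folds contiguous affine members into a single
matrix; mixed chains are returned as sequential callables.

`resample_volume` samples via linear or nearest interpolation
(scipy `map_coordinates`), fill value 0 outside the field of view; masks are
resampled nearest. `match_grid_xy` uses linear interpolation with *linear
extrapolation* at the borders so that affine intensity ramps are reproduced
exactly; the output grid is edge-aligned (same physical extent to within one
target voxel).

Intensity-based longitudinal registration is a rotation+translation model
(rotation about the reference-volume center) optimized by multi-start
Powell search on normalized cross-correlation, rejecting poses with < 50 %
overlap. Among numerically tied optima the lowest-parameter-norm solution
is returned, making the output deterministic. Failure (no pose with
positive correlation) raises with diagnostics rather than silently
returning identity.

Held-out registration error uses leave-k-out (default k = 1) over the
landmark set, pooling per-fold errors into one RMSE. The inter-rater
protocol pushes a 50-column × 50-row per-slice grid through both raters'
transform chains and reports the RMSE over a seeded random subsample.

## Voxel correlation

z-grouping averages complete groups of microscopy slices to the MRI voxel
depth; the grouping factor must be integer within 1 %, and a trailing
partial group is dropped with a warning (so total signal is conserved up to
that partial slab). For binary channels the grouped value is the volume
fraction in [0, 1].

In-plane density downsampling is area-weighted block averaging whenever the
scale factor is an integer ≥ 1 (within 1 %), because plain bilinear
sampling at large factors aliases and breaks the volume-fraction reading of
the result; non-integer factors fall back to bilinear sampling. Constant
fields and linear ramps are preserved exactly in both branches.

NAGM z-normalization uses per-volume mean and SD of the supplied
normal-appearing gray-matter mask (population SD; the mask is an input —
deriving it from microscopy is a curation step, not inferred here). A
configurable floor of 30 mask voxels triggers a warning below it.
Whether reference statistics should be per-slice is an open choice; this
implementation is per-volume.

T2\* mapping fits ln S = ln S₀ − TE/T2\* per voxel by weighted least squares
with weights S² (the delta-method variance correction for log-transformed
exponential decays). Fits with non-positive decay or T2\* above a 500 ms cap
are masked NaN. Noiseless synthetic decays are recovered to 1e-6; at SNR 50
the median recovery error is within 5 %.

Density bins are half-open [lo, hi) with the top bin closed at 100 %; the
"w/o glioma" bin is driven by the category mask (normal tissue), with the
recorded density forced to 0 there. The bin edges are 0, 5, 25, 50, 75,
100 %. Growth rate uses first-vs-last timepoint over the intersection of
all timepoint masks, in %/day (percentage points of density per day);
per-interval rates can be derived from the stored per-timepoint densities
in each record.

Group statistics: one-way ANOVA + Tukey HSD (statsmodels), Kruskal-Wallis +
Dunn post-hoc with tie-corrected z statistics and Bonferroni adjustment
(hand-written; the adjusted p is min(1, m·p_raw) over m pairs),
Mann-Whitney U and Welch's t (scipy).

## Vessel analysis

Local diameter is the maximal-inscribed-sphere thickness: the Euclidean
distance transform (world metric, anisotropic spacing respected) gives each
candidate center's inscribed radius, and every candidate sphere is painted
onto the voxels it covers, keeping max 2r per voxel. This is the exact
definition with no ridge pruning — heuristic prunes can under-paint — at
O(Σ ball volume) cost, which is acceptable at the mask sizes this package
targets. The estimate is exact to about one voxel for tubes whose axis
passes near voxel centers and systematically reads up to one voxel low for
strongly off-grid axes (the sphere must avoid background voxel *centers*).
The neighborhood operator of earlier interactive tools was unspecified;
maximal-inscribed-sphere is this package's stated choice, validated against
phantoms. The 30 µm filter keeps voxels with local diameter ≥ threshold; it
never adds voxels, is monotone in the threshold, and is idempotent for
well-separated structures.

Equivalence-margin stability compares per-category proportions at later
timepoints against a reference timepoint; a category is stable when its
maximum absolute deviation stays within the a-priori margin (default
±5 %, i.e. 0.05 in proportion units). PSE and the cohort CV use the sample
(n−1) standard deviation throughout.

Kymograph velocimetry converts streak slope to speed as
v = (|Δpx|·pixel_size)/(|Δlines|·line_interval); µm/ms equals mm/s, and
the sign (direction) is discarded. The automatic estimator shears the image
by candidate slopes (geometric sweep over 0.05–50 mm/s, then a local
refinement) and maximizes the variance of the time-averaged profile; a
peak-to-median response ratio below 2 is reported as indeterminate instead
of a number. Pixel count and pixel size of the scanned line are both free
parameters everywhere.

## Segmentation evaluation

Dilation for the Dilated Dice is a ball of *radius* equal to the tolerance
(default 50 µm — "added on both sides" read as radius, configurable), in
world units: a voxel joins D(M) iff its center lies within the tolerance of
a foreground voxel center. With 100 µm slice spacing a 50 µm ball adds no
out-of-plane neighbors; this is a property of the geometry, not a bug. MASD
is computed over all foreground voxels exactly as its symbol definition
states; a conventional surface-only variant (`surface_masd`) is provided
for comparison. Both metrics are implemented with distance transforms and
are tested to agree exactly with brute-force all-pairs references.

Training pairs are emitted at 25 µm in-plane / 100 µm slice spacing, labels
diameter-filtered then binarized, flips and 90° rotations applied
identically to image and label under one seed. Cross-validation folds are
assigned per subject (round-robin over a seeded permutation), so no animal
spans training and validation; fold sizes differ by at most one subject.
Network training itself is an external interface: pairs are exported in an
imagesTr/labelsTr layout and predictions re-imported; no weights ship with
this package. Visibility categories are human annotations consumed as
labels, never auto-classified.

## Lesion quantification

Connected components are found per ROI after thresholding, with default
26-connectivity in 3D and 8 in 2D (both exposed; classic particle-analysis
tools use 2D-8). Components are evaluated within each ROI independently, so
subdividing an ROI along component boundaries conserves counts and volumes.
"Per metastasis" means per ROI as drawn. Lesion classification by
perimetastatic shell signal uses a configurable shell width (default
100 µm, one MRI voxel) and z-score threshold (default −1, hypointense
rule); no published threshold exists for this decision, so the rule is an
explicitly logged parameter, not a reproduction.

## Phantoms: what they emulate, and what they do not

Vessel trees are recursive binary branchings with Murray-type radius decay
(r_child = r_parent·2^(−1/exponent), exponent default 3) and flow velocity
proportional to radius (max 8 mm/s at the root radius) — enough structure
to provide realistic bifurcation landmarks and a monotone flow–radius
relation, not a hemodynamic simulation. MRI contrast is a linear mixing
model: T2w/T2\*w = baseline − k_vessel·(vessel fraction) + k_tumor·(tumor
density) + Gaussian noise; TOF = baseline + k_flow·(flow-weighted
fraction) + noise, with defaults baseline 100, k_vessel 40, k_tumor 30,
k_flow 20 chosen to give clearly resolvable contrast at noise SD ≲ 1 % of
baseline. The contrast *signs* are built in so downstream statistics have
known directions; the coefficients are free knobs, not claims about tissue
physics (no Bloch simulation, no realistic PSF).

Smooth deformations are defined directly as the pull-back map
x ↦ x + u(x) from a coarse control grid with linear interpolation, scaled
so max‖u‖ equals the requested amplitude; landmark pairs are generated from
the same map and are therefore exactly consistent with the deformed volume.
Invertibility is enforced by rejecting amplitudes above half the field of
view.

The longitudinal series applies density(t) = clamp(density(0) + rate·t/100)
voxelwise — uniform additive growth, which makes the per-voxel rate exactly
recoverable and is deliberately simpler than any real growth law.

Consequences: passing phantom tests demonstrates that the *computational
chain* is correct (geometry, interpolation, normalization, metric
formulas, statistical arithmetic) under known ground truth. It does not
demonstrate robustness to the failure modes of real acquisitions —
shading and motion artifacts, imperfect landmark identification, vascular
pulsation, non-Gaussian microscopy noise, or genuine biological
heterogeneity.

## Problem sizes

Default test and acceptance runs use fields of view of 200–3200 µm,
microscopy at 10–15 µm voxels, MRI at 100 µm, 10–25 landmarks per scene,
kymographs of 300–400 lines × 128 px, and three phantom replicates per
registration summary — sizes chosen so the whole suite runs in well under a
minute while every bin, fold and metric path is exercised. All generators
scale to larger scenes through their parameters.
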