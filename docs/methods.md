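# Methods

## Problem setting

Multi-atlas segmentation registers several pre-segmented reference images
(atlases) to a patient image and fuses the transferred labels into one
consensus proposal. The deformable registrations dominate the runtime, so a
practical shortcut is to *link* pre-computed atlas-to-atlas registrations
through a single intermediate atlas that is registered to the patient at
runtime:

    T_{M<-I(l)<-F} = T_{M<-I_l} ∘ ... ∘ T_{I_1<-F}

where `l` counts the intermediate transformations. Linking trades runtime
for quality: every composed registration contributes its own error. This
package quantifies that trade and implements the fusion machinery; the
deformable registration itself is out of scope — transforms arrive from
files or from the synthetic generator.

## Transform model and conventions

- Transforms use the pull-back convention: they map fixed-space world
  coordinates (mm) to moving-space coordinates, so a warped image is
  `R(x) = M(T(x))`.
- Free-form deformations are cubic B-splines on a regular control lattice
  (default 8 mm in synthetic error fields' spirit; see below for the actual
  lattice spacings used). The lattice is padded three control points beyond
  the image domain: one point for full basis support inside the domain, two
  more so composed chains and inverse iterations that step slightly outside
  still see a smooth field.
- Composed transforms are materialized as dense displacement fields on the
  fixed grid, one trilinear interpolation per link; the exact functional
  composition is retained only as a test oracle. On the standard grid the
  two differ by well under 0.1 voxel except in the outermost border shell,
  where edge-clamping applies (out-of-grid field queries return the nearest
  border vector; out-of-support B-spline queries return zero displacement).
- Coordinates: voxel indices are 0-based, `world = origin + index *
  spacing`, axis-aligned. No direction-matrix support: files with oblique
  orientation are read with the matrix ignored and a warning.
- Images are resampled with linear (default) or interpolating cubic
  B-spline kernels; label maps and masks use nearest-neighbour sampling,
  which preserves label integrity at the cost of half-voxel boundary
  jitter. Warping distance maps and re-thresholding would reduce that
  jitter; it is deliberately not the default because it changes the
  artifact under test (label transfer as practiced).

## Scoring

- DSC(B1, B2) = 2|B1 ∩ B2| / (|B1| + |B2|); two empty masks score 1.0 (with
  a warning) so evaluation stays defined when a structure leaves the field
  of view, empty-vs-nonempty scores 0.
- Surface voxels are object voxels 6-connected to background; the image
  border counts as background.
- fMAD(d) is the fraction of the candidate's surface voxels whose nearest
  reference-surface voxel lies within d mm (3-D Euclidean, anisotropic
  spacing honoured). It is asymmetric by design.
- All distance computations use the exact Euclidean distance transform
  (scipy.ndimage), never chamfer approximations; distances are physical mm.

## Label fusion

Each atlas's warped structure mask is converted to a signed Euclidean
distance map (zero exactly on the 6-connected border voxels, negative
inside). Fusion is the voxelwise weighted mean

    D_fus = Σ_j w_j D_j / Σ_j w_j

and the consensus segmentation is `D_fus <= 0`. The `<=` convention makes
single-input fusion reproduce its input exactly (border voxels carry 0); a
consequence of the discrete zero level is that an arbitrarily small positive
perturbation removes the border layer, so consensus-vs-outlier convergence
saturates at the one-layer-eroded shape rather than exactly 1.0 DSC.
Atlases whose warped mask is empty for a structure are dropped from that
structure's fusion with a logged warning.

Weights come from the similarity of each atlas's registered image to the
fixed image:

    w_i = 1/2 (1 − erf((k/s)/√2 · (SIM_best − SIM_i)))

Similarity is normalized cross correlation over a band region `D <= r`
around the structure (fixed-image frame, where all atlases are comparable);
default r is 0 mm for the sharp-boundary mandible-like structure and 10 mm
otherwise, configurable. `k/s = 0` recovers equal weighting; the best atlas
always receives 1/2, ties all receive 1/2. Rather than estimating k (the
regression slope of DSC on SIM) and s (the residual sd) directly, the ratio
is swept through the slope angle θ:

    k/s = √N tanθ / sqrt(ss_DSC + ss_SIM tan²θ − 2 ss_SIM,DSC tanθ)

with x ↔ SIM, y ↔ DSC (so that at the ordinary-least-squares angle the
expression reduces exactly to slope / residual-sd when the residual sd uses
the 1/N normalisation). The calibration sweep covers −89°..+89° in 1° steps
by default, scoring mean fused DSC over leave-one-out cases; negative angles
(negative k/s, up-weighting dissimilar atlases) are evaluated for the curve
but the reported operating point is restricted to k/s ≥ 0, the weight
function's domain.

## The leave-one-out linking experiment

For N atlases, each in turn is the "patient": all ordered (fixed, moving)
pairs give N(N−1) direct registrations; one-link chains through a distinct
intermediate give N(N−1)(N−2) combinations; longer chains (up to N−2
distinct intermediates, i.e. N−1 composed transformations) are uniformly
sampled without replacement, deterministically per seed. Relative DSC change
is computed on matched (fixed, moving, structure) pairs, in percent, linked
vs direct. Fused cases follow the design of one fusion per (fixed,
intermediate) pair: the moving atlases contribute labels through the linked
transform, the intermediate contributes its own labels through its direct
transform to the fixed image. Summaries are medians with 25th/75th
percentiles (linear-interpolation quartiles); distributions are compared
with the two-sided Wilcoxon rank-sum test (exact for small tie-free
samples, tie-corrected normal approximation otherwise); the decay of median
DSC with link count is summarized by an ordinary-least-squares line whose
intercept extrapolates to zero-registration quality.

## Synthetic study population

The generator replaces the clinical cohort with a digital phantom: a
64×64×48 grid at 2×2×3 mm (anisotropic, slice thickness larger than the
in-plane pixel) carrying eight structures that mirror a head-and-neck
organ-at-risk set — paired parotid-like and submandibular-like ellipsoids, a
mandible-like arc (torus section), a medulla-like tube, and paired slab-like
node levels — with distinct intensities on a noisy background (Gaussian
noise, sd 5 intensity units).

Subjects are generated by pulling the template back through random smooth
cubic B-spline deformations g_i. Defaults, chosen once:

- inter-subject deformation: 4 mm RMS displacement on a 20 mm control
  lattice. The coefficient spread is capped at 0.4 × control spacing (and
  the sampled Jacobian determinant checked positive, regenerating on
  failure) so deformations stay invertible; 4 mm at 20 mm spacing is the
  largest amplitude compatible with that cap, and gives inter-subject
  structure overlaps comparable to distinct patients.
- emulated registration error: 2 mm RMS on a 12 mm lattice (the 12 mm
  spacing again follows from the invertibility cap at 2 mm amplitude). Each
  pairwise "registration" is the exact inter-subject map composed with an
  independent error field, deterministic per (seed, i, j).

Atlas labels are rasterized analytically — the organ indicator evaluated at
g_i of each voxel center — rather than by resampling the template labels,
so label voxelization error enters once (at transfer), not twice. Exact
pairwise maps T_{j<-i} = g_j⁻¹ ∘ g_i use a numerical inverse computed by
damped-free fixed-point iteration (x ← y − d(x)) on a 16 mm-padded grid,
accurate to ~0.1 mm; composing ground-truth maps through an intermediate
reproduces the direct ground-truth map to under half a voxel away from the
clamped border shell, so any observed decay in linked experiments is
attributable to the injected registration error (the zero-noise control
measures the plumbing cost at ~0.2 % median absolute DSC change).

With 2 mm RMS error the direct-registration DSC medians land at 0.73–0.88
per structure — the plausible clinical range, leaving headroom for
degradation. What the phantom does *not* emulate: CT physics and
Hounsfield calibration, pathology-induced anatomy changes, intensity
inhomogeneity between subjects, and real registration-error spatial
structure (errors here are smooth, stationary random fields). Passing tests
therefore demonstrate correctness of the machinery and the direction and
rough magnitude of linking effects, not clinical performance numbers.

## Problem sizes used in the standard runs

The standard experiment (tests and the acceptance script) uses N = 6
subjects, link counts 0..4 intermediates (one to five composed
transformations; with six atlases at most four distinct intermediates
exist), full enumeration of the 30 direct and 120 one-link cases, 30
sampled chains per longer link count, and all structures; fused scoring
covers every (fixed, intermediate) pair. Full one-link enumeration matters
for the individual-vs-fused spread comparison: subsampled one-link chains
add enough estimator noise to blur the (small) variance-reduction effect at
this cohort size. The calibration sweep in the
acceptance script uses a 2° angle step over −89°..89°. The library defaults
are 100 chains per link count and a 1° step.

## Known limitations

- No inverse-consistency or diffeomorphism enforcement; invertibility of
  synthetic fields is statistical (coefficient cap + Jacobian check).
- Composed fields are stored at image resolution; the outermost border
  shell of a composed field is edge-clamped and less accurate.
- The discrete iso-level-zero convention ties the fused border to voxel
  centers; sub-voxel consensus surfaces are not represented.
- Band-region NCC assumes the warped atlas images and the fixed image share
  an intensity convention (true for the phantom; real CT pairs may need
  histogram alignment first).
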