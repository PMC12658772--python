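# Methods

This note records the models the package implements, the parameter
choices that matter, what the phantom generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Geometry and preprocessing

All computation happens in a "straightened" cord representation: volumes
are resampled to 0.5 mm isotropic spacing (trilinear for intensities,
nearest neighbour for masks, voxel centres at `(index + 0.5) * spacing`,
output shape `ceil(extent / spacing)` per axis), then each axial slice is
cropped to a 48×48 window centred on the integer-rounded cord centroid of
that slice and the windows are stacked along z. Axis order is fixed to
LAS+ at load time (x = left/right, y = anterior/posterior,
z = superior/inferior), so sagittal planes are planes of constant x and
the through-slice direction is always axis 2.

Open choices resolved here: window centres for slices without cord
between two cord-bearing slices are linearly interpolated from the
flanking centroids; slices before the first and after the last
cord-containing slice are dropped; window borders are zero-padded. No
inverse (un-straightening) transform is provided — evaluation operates in
straightened space. A curved-planar reformation along a fitted centreline
spline would be more faithful to anatomy but is out of scope; the
per-slice crop keeps masks voxel-exact, which the statistics below rely
on.

## Contrast model

The lesion/neighbourhood contrast ratio C_p uses *mean* intensities (the
standard intensity statistic in MR), with the neighbourhood built by
dilating the lesion with a 5-voxel disc within each sagittal slice
(because in-plane spacing of the source sagittal acquisitions is much
finer than the slice spacing), subtracting the lesion, and intersecting
with the cord eroded by a 1-voxel disc to keep bright CSF out. The sign
convention makes hyperintense lesions positive.

Contrasts pool into a truncated normal ψ(μ̄, σ̄, a, b): sample mean,
sample SD (ddof = 1), a = 20th percentile (linear-interpolation
percentile, stated so tests can be exact), b = 1.0 (the upper side is
effectively untruncated). Sampling is by inverse CDF on a seeded uniform
stream — exact, reproducible, no rejection loop. A degenerate model
(σ̄ = 0) returns the clamped mean and still consumes one uniform so call
sequences stay aligned across configurations. Correlations between
contrast, spatial gradient and within-lesion variance are deliberately
not modelled; the three appearance components are independent.

## Intensity synthesis

Three composable steps, selectable as increase-only / +gradient /
+gradient+blur:

1. **Flat increase** — `I* = (1 + c) I` inside the candidate mask. The
   within-mask mean ratio equals 1 + c to machine precision; this is the
   exactness contract the tests assert at 1e-12 relative.
2. **Gaussian gradient** — per-axis decay scales σ_m ~ U(l_m/8, l_m)
   adapt the profile to the mask's extent (sharp decay for small lesions,
   nearly flat for σ_m ≈ l_m); the amplitude A normalises the *mask-mean*
   relative increase to c (checked at 1e-9 relative). A printed
   alternative normalisation (profile summing to 1 over the mask) is
   inconsistent with this amplitude definition; the amplitude definition
   is implemented because it preserves the mean-contrast contract of step
   1. A floor of 0.015 on the relative increase guarantees some signal
   over the whole mask when c is small and the decay sharp. The floor is
   applied before the blur. The profile centre and lengths are recomputed
   on the *clipped* mask (the mask that actually receives intensity), not
   the pre-clip shape.
3. **Local blur** — Gaussian, σ = 0.67 voxels, kernel radius 2 voxels
   (0.333 mm and 1 mm at 0.5 mm spacing), computed over the mask's
   bounding box padded by the kernel radius with reflective boundaries,
   written back only at mask voxels. This reduces within-lesion variance
   (matching the observation that lesions are more homogeneous than their
   neighbourhoods) while leaving every outside voxel bit-identical, so
   the contrast statistics of neighbouring tissue are untouched.

Because the blur mixes boundary voxels with unmodified surrounding
tissue, the re-measured contrast of a fully synthesised lesion sits
systematically *below* the sampled c — measured on the phantom geometry:
mean shortfall ≈ 0.19 c, worst ≈ 0.4 c for lesions under ~50 voxels. The
tests freeze these empirically measured bounds rather than a nominal
symmetric tolerance. Users who need exact mean contrast should disable
the blur.

## Shapes and placement

The shape library filters to volumes within the [10th, 90th] percentile
band (inclusive; single-record and all-equal libraries bypass the filter
so the eligible set is never empty) and draws uniformly. Augmentation
applies, with probability 0.5, an isotropic scale U(0.9, 1.1) and
rotations (U(−5,5), U(−5,5), U(−45,45)) degrees about the x/y/z axes
about the mask centroid, then erosion (p = 0.25) or dilation (p = 0.25)
by a radius-1 ball. Binary resampling is nearest-neighbour through an
explicit inverse coordinate map with `rint` rounding — hand-rolled rather
than a spline-based transform so the rounding rule is exact and testable
against a coordinate-set oracle. Scaling is isotropic (one factor), the
rotation is composed as Rz·Ry·Rx, and an augmentation that empties the
mask is redrawn up to 10 times before falling back to the unaugmented
shape.

Placement keeps the source lesion's in-plane position (cord anatomy is
roughly aligned after straightening), randomises the centroid's z
uniformly over positions where the mask fits, and clips to the cord
eroded by a 1-voxel sagittal disc. Successive insertions in one volume
must not overlap (up to 10 redraws, then the lesion is skipped): a lesion
inserted on top of another would corrupt the per-lesion contrast
contract. A `fixed_axial` flag keeps the source z position for
position-ablation experiments. No spatial prior map is used for
placement.

## Comparison transforms

Both baselines standardise intensities to mean 0, SD 1 before mixing, so
scale differences between acquisitions do not produce spurious hyper- or
hypointensities (they still can — a locally darker source yields a
hypointense insertion, a documented failure mode the tests assert rather
than prevent).

*Carving insertion* copies the source region R = {v : d(v) ≤ λ}, where d
is the signed Euclidean distance to the lesion boundary (strictly
negative inside), into the target at the original position; R equals the
lesion mask at λ = 0 and is nested in λ. The λ law is not fixed by any
published value; the default is an equal mixture of U(d_min/2, 0)
(shrink) and U(0, 2 voxels) (grow), exposed as parameters.

*Target-load insertion* extracts one 48×48×b patch per connected lesion
(b = the lesion's z extent), then inserts augmented patches at random z
positions — flips (p = 0.5 per axis), isotropic scaling U(50 %, 180 %)
(p = 0.5), rotation about z up to ±89° and about x/y within ±5°
(p = 0.5), elastic deformation from a 7³ control grid with displacements
up to 4 voxels (p = 0.5), a gamma transform with exponent exp(U(−0.3,
0.3)) on the patch's shifted non-negative range, and additive Gaussian
noise with σ = 0.1 on the standardised scale — until the total inserted
load reaches a target drawn from U(p5, p95) of the library loads, or a
budget of 50 draws is exhausted. Inserted masks are clipped to the eroded
cord and may not overlap previous insertions; the returned volume is in
standardised space (where the patches live). The gamma/elastic parameter
values are explicit knobs, not claimed reproductions of any reference
implementation; only the displacement bound, noise level and rotation
limits are fixed by the protocol this follows.

## Evaluation

Components are 26-connected (fixed here so tests are exact; lesion
counting conventions vary) and carry the maximum voxel score (mean
aggregation is available behind a flag). The threshold sweep is
dataset-pooled: one global component-score threshold, swept over every
distinct score, with a sentinel above all scores so FPPI 0 is always
attainable. Matching is greedy by descending IoU, one-to-one, ties broken
by component label, and a pair matches only if IoU > 0.2 *strictly* — an
IoU of exactly 0.2 is never a true positive. Sensitivity at an FPPI level
is the best sensitivity over thresholds with FPPI ≤ level (no
interpolation between thresholds), and the FROC score averages the five
levels {0.25, 0.5, 1, 2, 3}. The FPPI = 1 operating point takes the
threshold with FPPI closest to 1 from below (ties toward higher
sensitivity) and reports lesion sensitivity/precision/F1, pooled voxel
Dice, and Dice restricted to GT/predicted components with non-zero mutual
overlap (separating segmentation quality from detection quality). An
alternative any-overlap detection criterion is provided for comparison
with click-based reader studies. `epoch_iterations(n, p, b) =
ceil(2np/b)` is a planning helper for balanced real/synthetic training
epochs.

## Phantoms

The phantom generator emulates exactly the statistical structure the
method assumes: a darker cord tube (radius 4 mm) with a smooth axial
wobble (≤ 2 voxels), a bright CSF sheath (1.5 mm) as the hyperintense
confounder, background, optional additive Gaussian noise (default SD 2
against cord intensity 100), and ellipsoidal lesions (semi-axes 1–2.5 mm
in-plane, 2–6 mm along z) planted with *flat* multiplicative contrast
drawn from ψ(0.17, 0.11, 0.077, 1.0) — the reported contrast statistics
of real cord lesions, with the lower bound at that normal's 20th
percentile. Flat planting makes contrast capture exact on noiseless
phantoms (the measured C_p of a planted lesion equals the planted c to
float precision when its neighbourhood is uniform cord), which is why
planted lesions are kept far enough apart that their 5-voxel
neighbourhoods stay clean. The default z extent is 200 voxels (real
straightened cords are typically longer; tests use 80–120 for speed —
all contracts are extent-independent).

The phantom does **not** model MR physics: no bias fields, no motion or
CSF-flow artefacts, no partial-volume mixing, no multi-lobed lesion
texture. Passing tests therefore demonstrate the correctness of the
synthesis and evaluation machinery and the recoverability of the
contrast model under the method's own assumptions — not performance on
clinical images.

## Reproducibility and limits

Every random operation takes a `numpy.random.Generator`; identical seeds
give bit-identical volumes, labels and metrics. Dataset builders spawn
one child stream per volume so per-volume outputs do not depend on
processing order. Masks are stored as uint8 and round-trip bit-exactly
through NIfTI; intensities are stored as float32 (≤ 1e-6 relative
round-trip error) and processed as float64 in memory.

Known limitations: the contrast, gradient and homogeneity components are
sampled independently; placement ignores anatomy beyond the cord mask;
the blur lowers realised mean contrast below the sampled factor (see
above); and the straightening omits any centreline smoothing a full
curved-planar pipeline would apply.
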