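# Methods

## The problem

Micro-CT of the lung at peak inspiration shows blood vessels as water-dense
tubes against air-filled parenchyma, so the pulmonary vasculature can be
segmented and measured *without* an injected contrast agent.  The catch is
turning an image-processing byproduct — the Gaussian kernel scale at which a
tube-enhancement filter responds most strongly — into a physical vessel
caliber.  This package implements that conversion and the synthetic-phantom
calibration and FWHM validation machinery around it.

## Multi-scale vesselness and S_MAX

At kernel scale `S` (voxels) the volume's Hessian is computed with
Gaussian-derivative kernels of standard deviation `S`, each second derivative
multiplied by `S**gamma` (gamma-normalization, default `gamma = 2`) so
responses are comparable across scales.  Per voxel the eigenvalues are sorted
by magnitude, `|lam1| <= |lam2| <= |lam3|`, and combined into Frangi's
vesselness

    V_S = (1 - exp(-R_A^2 / 2 alpha^2)) * exp(-R_B^2 / 2 beta^2)
          * (1 - exp(-S2 / 2 c^2)),

with `R_A = |lam2|/|lam3|` (plate vs. tube), `R_B = |lam1|/sqrt(|lam2 lam3|)`
(blob), `S2 = sum(lam_i^2)` (structureness), and `V_S = 0` wherever
`lam2 > 0` or `lam3 > 0` for bright tubes.  The *probability volume* is the
pointwise maximum of `V_S` over scales, and `S_MAX` is the scale attaining
it.  For an ideal cylinder the gamma-normalized response at the centerline
peaks near `S ~ r/sqrt(2)`, i.e. `S_MAX ~ 0.35 * diameter`, which is why
`S_MAX` works as a caliber surrogate; the phantom calibration below measures
the constant instead of assuming it.

### Parameter defaults and the choice of `c`

`alpha = beta = 0.5` are the standard sensitivities for the two geometric
ratios.  The structureness sensitivity `c = "auto"` resolves to **half the
maximum gamma-normalized Hessian Frobenius norm over the volume and over all
scales**, found in a first streaming pass (a second pass then evaluates
`V_S`).  The across-scales part is essential: normalizing each scale against
its own maximum makes the structureness term scale-relative, the response at
a tube centerline then never decays with `S`, and the argmax runs to the
largest scale regardless of tube size (we verified this directly: a 5 px
tube reports `S_MAX = 15` under per-scale normalization, vs. 2 with a global
`c`).  A fixed numeric `c` can be supplied instead.  With auto-`c` the
argmax is invariant to multiplying the volume by a positive constant.

Scales default to the integers 1–30 voxels.  Argmax ties resolve to the
smallest scale.  Voxels closer than `3 * S_MAX` to a volume border are
flagged in a validity mask.

### Numerical implementation

Gaussian derivatives are evaluated in the DCT-II/DST-II domain: the cosine
basis diagonalizes Gaussian smoothing under half-sample-symmetric reflective
extension (identical boundary handling to spatial-domain `reflect`
convolution), odd derivative orders move to the index-shifted sine basis.
One forward DCT is shared by all scales, and partial inverse transforms are
shared across the six Hessian components of a scale.  At `S = 30` on a
~30-megavoxel volume this is roughly two orders of magnitude cheaper than
truncated spatial kernels on one core.  Agreement with `scipy.ndimage`
Gaussian derivatives (the independent oracle in the test suite) is ~1e-3
relative, the truncated-kernel difference.  Eigenvalues come from a
vectorized closed-form (trigonometric) symmetric-3x3 solver, checked against
LAPACK to 1e-8.

Voxels whose Hessian norm is below `0.02 * c` are skipped during the
per-scale update; their structureness term is bounded by `2e-4`, so their
vesselness is negligible against any useful segmentation threshold.  The
cutoff is exposed (`response_cutoff`, 0 disables).

## Segmentation and the centerline tree

The probability volume is thresholded (default 0.05) and grown from seed
points by 26-connected flood fill.  The mask is thinned to a one-voxel-wide
centerline by topology-preserving 3D thinning, converted to a graph over the
26-neighborhood, reduced to a maximum-probability spanning forest (so each
cycle loses its lowest-probability edge), and pruned of terminal spurs
shorter than 3 nodes (switchable).  Branches are maximal degree-2 paths;
generations count from a root at the endpoint with the largest mapped
`S_MAX` (the thickest, most proximal end).

One robustness note: sub-iteration thinning can annihilate *perfectly*
mirror-symmetric even-width objects (an axis-aligned even-diameter cylinder
centered between voxels) instead of reducing them to a line.  Real masks are
never that symmetric, but synthetic ones can be, so when the thinned result
under-covers its mask the thinning is retried with a deterministic one-voxel
surface groove carved along an axis, which breaks the symmetry without
moving the centerline.

## Calibration on the tube phantom

The phantom holds 10 parallel tubes with diameters geometrically spaced from
3.14 to 62.8 px, all rotated by extrinsic (x, y, z) = (30°, 15°, 0°) applied
x-then-y-then-z about the volume center, rasterized with 3x supersampled
partial-volume edges (foreground 1, background 0; the method is
contrast-ratio based so absolute scaling is irrelevant).  Layout is a single
row along the rotated x direction with an alternating transverse zigzag,
sized so that (a) no two tube surfaces come closer than the largest tube
diameter in 3D and (b) at the phantom's own view angle (15°, its y-rotation,
at which the projected tube axes run exactly along image rows) the projected
strips are separated by at least ~0.56 of the largest diameter.  Volume
dimensions are derived from the layout ((136, 352, 640) voxels for the
default) and satisfy "at least twice the largest diameter per axis".

Per tube, 25 replicate measurement lines are placed perpendicular to the
projected axis, stepped 2 px apart along the tube around its mid-volume
position.  Each replicate yields a pair:

* `D_PROJ` — FWHM of the line profile on the maximum intensity projection
  (the silhouette of a cylinder has width equal to its diameter at any
  oblique view, so `D_PROJ` estimates the generated diameter directly);
* `S_MAX` — the maximum value on the same line in the projection of the
  tree-mapped `S_MAX` attribute (nearest-pixel sampling; the splat is
  dilated to 3x3 so a 0.25 px-stepped line cannot slip between pixels).

Replicates average to one point per tube; ordinary least squares of `S_MAX`
on `D_PROJ` gives the calibration (slope ~0.35 scale units/px, R > 0.99
under the defaults).  The conversion to physical caliber is the exact
algebraic inverse scaled by the effective voxel size:

    D_CT = (S_MAX - intercept) / slope * voxel_size.

`S_MAX` values at or below the intercept are non-physical and reported as
NaN.  The intercept is fitted freely (a forced-zero option exists); both
regression orientations are reported in comparisons.

## FWHM caliber measurement (2D angiography path)

Bolus sequences are background-corrected by subtracting each frame from the
temporal mean (static anatomy cancels; darker iodinated vessels become
positive enhancement), smoothed with an edge-truncated temporal moving
average (default 5 frames either side), and the frame with the largest total
enhancement is selected (ties: earliest).  A caliber reading samples 5
parallel lines 1 px apart by bilinear interpolation at 0.25 px steps; the
baseline is the lower of the two outer-10% tail means (robust when a line
ends near another vessel); the width is the distance between the two
half-level crossings nearest the peak, each localized by linear
interpolation; per-line widths average into the reading, and lines without
two crossings are dropped and counted.  Sub-pixel localization matters
because tube diameters down to ~3 px are measured.

## Synthetic data: what it does and does not emulate

The generators produce the geometry the method is sensitive to — tube
caliber, partial-volume edges, arbitrary orientation, branching topology
with per-generation diameter ratios, bolus time courses with ramp/decay and
i.i.d. Gaussian noise — under known ground truth.  They do **not** model
beam hardening, detector noise spectra, cone-beam divergence (projections
here are parallel-beam orthographic; magnification is absorbed into the
21.9 µm effective voxel size), cardiac/respiratory motion, or tissue
inhomogeneity.  Passing tests therefore demonstrate correctness of the
measurement chain and its calibration on ideal tubes, not in-vivo accuracy;
the in-vivo comparison (D_CT vs. D_ANG in live animals) requires real data
by construction, and a parameter-recovery experiment on a branching phantom
(r >= 0.9, midpoint error <= 15% for 5–50 px branches) stands in for it.

## Problem sizes

The shipped test suite runs the calibration at a reduced setting (6 tubes,
3.14–30 px, scales 1–15, ~2.7-megavoxel volume) and the tree recovery at
160^3; the linear relation makes slope and R insensitive to the truncation
of the diameter range, which the full-scale run (`scripts/acceptance.py`,
10 tubes to 62.8 px, scales 1–30) confirms.  Branch calibers on trees are
read as the mean `S_MAX` over the central half of each branch, which
averages out the integer-scale quantization the same way the 25-replicate
averaging does for tubes.

## Known limitations

* Integer scale sampling quantizes `S_MAX`; single-voxel readings carry up to
  half a scale step of error (mitigated by replicate/branch averaging).
* `S_MAX` measures the outer caliber of the bright structure; against
  contrast angiography (which sees the lumen) a positive intercept is
  expected in comparisons.
* Parallel-beam projection ignores cone-beam divergence; relative in-plane
  calibers are unaffected, absolute scale rides on the effective voxel size.
* The flood-fill threshold (0.05) and Frangi sensitivities are conventions,
  not fitted constants; the calibration absorbs their influence on the
  S_MAX-to-caliber mapping, which is why calibration and measurement must
  use the same parameter set.
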