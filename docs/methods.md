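# Methods

`spectrc` studies how the placement of the six fillable spheres in a
NEMA IEC body phantom changes the recovery coefficients (RCs) measured
by quantitative Lu-177 SPECT/CT, and what that spread does to
recovery-curve fits and partial-volume corrections (PVC).  Everything
is simulated: the package generates phantoms, projects them with an
analytic SPECT forward model, reconstructs with OSEM, and analyzes the
result.  This note records the model, its assumptions, the defaults,
and what the pipeline can and cannot say about real measurements.

## Phantom model

The body is the IEC outline approximated by a 300 x 230 mm rounded
rectangle (two 115 mm half-discs joined by a 70 mm flat section),
180 mm long, water-filled.  Six spheres sit on a 57.2 mm-radius ring in
one transaxial plane, 60 degrees apart, position 1 at 12 o'clock and
positions counted clockwise seen from the gantry front.  Two variants:

* **NEMA PET** - diameters 10, 13, 17, 22, 28, 37 mm;
* **NEMA SPECT** - the 10 mm sphere replaced by a 60 mm sphere
  (13...60 mm), the variant proposed for Lu-177 harmonization.

Spheres are filled at 2 MBq/mL; the background is cold (zero
concentration) by default.  Sphere walls and the lung insert are
ignored; attenuation is water-equivalent, mu = 0.0137/mm at 208 keV,
and the attenuation map is therefore identical for all sphere
arrangements.  Assigning the six diameters to the six positions gives
6! = 720 arrangements; a sagittal mirror pairs them into 360
equivalence classes, which are kept as metadata only because a real
detector orbit need not be mirror-symmetric.

Voxelization uses fractional occupancy: each voxel in a sphere's
bounding box is subdivided 4x per axis and the fraction of subvoxel
centers inside the sphere is stored.  Boundary errors cancel, and the
occupancy-summed volume converges monotonically to the analytic volume
as the subdivision is refined (checked at factors 1, 2, 4; at 4x and a
2.4 mm grid the 60 mm sphere volume is accurate to < 0.01 %).

With the 57.2 mm ring, adjacent sphere centers are one ring radius
apart, so the surface gap between the 37 and 60 mm spheres as direct
neighbors is 57.2 - 48.5 = 8.7 mm.  (Reported values for the physical
phantom are closer to 8.5 mm; the exact center geometry of a given
phantom copy, known only from its CT, differs slightly from the nominal
layout.  We use the nominal layout and do not force agreement.)

## Forward model

Photon transport is replaced by a rotation-based analytic projector.
For each view the activity grid is mapped into the detector frame by a
sparse bilinear *splatting* matrix (each voxel distributes its emission
with weights summing to one, so counts are conserved exactly); the
transposed matrix is the exact backprojection.  In the detector frame:

1. **Attenuation.**  Beer-Lambert survival factors are accumulated
   through the rotated mu-map from each voxel to the detector, with the
   emitting plane contributing half its own thickness.
2. **Distance-dependent resolution.**  Each depth plane is convolved
   with a Gaussian of FWHM(D) = sqrt(intrinsic^2 + (slope * D)^2),
   D being the plane-to-detector distance.  Defaults: intrinsic 4 mm,
   slope 0.055 (about 14 mm FWHM at 250 mm), standing in for a
   medium-energy low-penetration collimator at 208 keV; both are
   configurable.  The convolution runs in the Fourier domain with the
   DFT of an explicitly truncated, normalized Gaussian kernel on a
   zero-padded domain: the kernel is non-negative (no ringing at
   sub-voxel sigma) and even, so the blur is exactly self-adjoint and
   the projector/backprojector pair passes the adjoint identity to
   floating precision.
3. **Depth sum** onto the detector bins (optionally block-rebinned).

The orbit is auto-contoured: per view, the radius is the body's support
extent along the detector normal plus a margin (default 25 mm).  Views
from below receive an extra stand-off proportional to the downward
component of the view direction (default 60 mm), emulating the patient
table; this breaks the top/bottom symmetry so the detector's closest
approach is uniquely at the top, as on a real system where the couch
and its rail limit posterior contouring.  Two heads 180 degrees apart
acquire 2 x 60 views over 360 degrees.

**Scatter** is an effective model, not transport: the true scatter in
the 20 % photopeak window at 208 keV is a scaled broad convolution of
the primary (fraction k = 0.2, kernel FWHM 60 mm).  The two adjacent
10 % windows are populated so that the triple-energy-window (TEW)
trapezoid reproduces the injected scatter exactly in expectation; after
Poisson noise the TEW estimate is unbiased but noisy, which is the
property the reconstruction has to live with, as in practice.

**Counts.**  A global calibration factor scales the projections so the
mean main-window total is 25 kcts per detector and view (the
harmonization protocol's count level) for the reference arrangement at
2 MBq/mL; the factor is then held fixed for every arrangement, like a
fixed camera sensitivity.  Poisson noise is drawn independently per bin
and window with one seed per projection set; permutation sweeps derive
per-arrangement seeds as master seed + arrangement index, making every
sweep bit-reproducible.

## Reconstruction

OSEM with the multiplicative update
x <- x / (A_s^T 1) * A_s^T [ y_s / (A_s x + s_s) ], subsets interleaved
by stride, scatter entering additively in the denominator (preserves
the Poisson model and non-negativity; no pre-subtraction).  The initial
image is a uniform positive constant matched to the total counts;
voxels with zero subset sensitivity are excluded from updates rather
than divided by zero.  Two arms:

* **OSEM_noRR** - attenuation only in the system matrix; 10 subsets,
  snapshots at 10...100 updates (analysis at 50);
* **OSEM_RR** - the distance-dependent PSF additionally modeled in the
  matched projector/backprojector pair; snapshots at 20...200 updates
  (analysis at 200, the highest run, since resolution modeling slows
  convergence).

Reconstruction and simulation share the projector implementation and,
in the desk preset, the grid.  This is a matched-model ("inverse
crime") setup: it removes every systematic discrepancy between the data
and the noRR/RR system models except the one under study - whether the
distance-dependent PSF is modeled - plus noise and TEW-estimation
error.  The RC levels are therefore optimistic relative to a physical
measurement (no septal penetration, no detector energy response, no
model mismatch), but the *contrasts* the study is about (position
dependence, noRR vs RR, neighbor effects) survive, which is what the
structural checks assert.

## Recovery analysis

Reconstructions are tri-linearly interpolated onto the high-resolution
mask grid (interpolating the image up rather than the mask down avoids
the coarse-voxel sampling artifact), and

RC = sum(activity * occupancy) * voxel volume / nominal activity

per sphere, nominal = concentration x analytic volume.  Per
(phantom, arm, updates, diameter) cell the spread over arrangements is
theta_RC = (RC_max - RC_min) / mean RC, with the extreme arrangements
retained (including the diameters of the two ring neighbors and their
surface gaps).  For small structured sweeps, `position_mean_rc` gives
the mean RC per ring position: with only a few records per position the
single-record argmax is dominated by counting noise and neighbor
composition, so the per-position mean is the statistic the acceptance
checks use when asking *which position* yields the highest recovery.

Recovery curves use f_RC(d) = (1 + (beta/d)^gamma)^-1, fitted by
unweighted non-linear least squares with a multistart fallback
(beta ~ the 0.5-crossing diameter, gamma = 2; bounds beta <= 20 cm,
gamma <= 10).  **Diameters are in centimeters for fitting**, which puts
beta in the 1-3 range; gamma is dimensionless.  Degenerate input (all
RCs equal) is flagged non-identifiable rather than fitted.  Ensembles
of fits are summarized by the pointwise mean curve, the sample standard
deviation (N-1), the pointwise envelope, and the parameter variations
theta_beta, theta_gamma (range over mean).

Agreement between two curve sets indexed by the same configurations is
measured per diameter by delta (mean absolute reference-vs-test
deviation) and Delta (mean absolute deviation of the reference curves
from their own mean); delta < Delta means a simulation tracks each
arrangement better than one averaged curve would.

The PVC worked example evaluates two measured fits (Standard:
beta = 1.37, gamma = 2.44; Standard-120: beta = 1.27, gamma = 3.21) at
the 10 mL lesion diameter d = 2.67 cm.  RCs are quoted rounded to two
decimals and the correction factors are the reciprocals of the rounded
RCs - the convention such examples are reported in - giving 0.84/0.92,
1.19/1.09, and a 9.2 % difference in corrected activity from sphere
arrangement alone; the unrounded values are reported alongside.

## Problem sizes

The full-scale campaign (2 phantoms x 720 arrangements, 256^3 grids at
2.4 mm) is a cluster workload.  The package's presets:

* **desk** (default): NEMA SPECT phantom, 24 structured arrangements
  (six rotations of four orderings - ascending, descending, the
  alternating "Standard" pattern, and one with the two largest spheres
  adjacent - covering every position-diameter pair), 72 x 72 x 26 grid.
  The desk preset deliberately *keeps* the two conditions the
  small-sphere convergence behavior turned out to depend on - the
  4.8 mm reconstruction voxel and the 2 x 60-view sampling - and
  economizes only on the transaxial/axial field of view, the mask grid
  (2.4 mm instead of 1 mm), and the number of arrangements.  A sweep
  runs in minutes on one core.
* **full**: 2.4 mm simulation / 4.8 mm reconstruction grids, 128
  transaxial bins, 1 mm masks, for full-scale runs.

## Numerical choices and edge cases

* Interpolation order 1 everywhere (voxelization is handled by
  occupancy masks, not interpolation).
* OSEM denominator floored at 1e-12; all-zero data legitimately produce
  the all-zero image after one update.
* TEW estimates are clipped at zero; floating-point ringing from the
  FFT blur (~1e-16) is clipped before Poisson sampling, while genuinely
  negative inputs still raise.
* Fits are attempted from a deterministic multistart grid; r^2 is
  computed on untransformed RCs.
* Reported comparisons round half-even to two decimals.

## Limitations

* No photon transport: septal penetration, detector energy response,
  dead time, and object-dependent scatter spectra are absent; the
  scatter model is constructed to be TEW-consistent rather than derived
  from physics.  Absolute RC levels should not be compared against
  physical measurements - the structural findings are the target.
* The matched-model setup makes RR reconstructions converge toward
  truth by construction; RR RCs at 200 updates are upper bounds on what
  an approximate vendor PSF model would achieve.
* The orbit couch term is a one-parameter stand-in for real contouring
  hardware; real orbits come from the scanner's DICOM headers.
* The smallest SPECT sphere (13 mm) sits at the resolution limit; its
  RC retains the largest noise and the slowest convergence, and on the
  desk preset its noRR recovery still creeps by a fraction of a percent
  between 50 and 100 updates.
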