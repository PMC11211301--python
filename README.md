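# spectrc

Sphere-position dependence of recovery coefficients in quantitative
Lu-177 SPECT/CT — a simulation pipeline for NEMA body-phantom sphere
permutations.

## The problem

Quantitative Lu-177 SPECT/CT is calibrated and harmonized with the
NEMA IEC body phantom: six fillable spheres on a ring, imaged at known
activity concentration, yielding one recovery coefficient (RC) per
sphere — the image-based activity divided by the true activity.  RCs
feed accreditation ranges and recovery-curve-based partial-volume
corrections (PVC) of lesion activities, and hence absorbed-dose
estimates.

SPECT resolution, however, is not spatially invariant: the detector
auto-contours the body, so blur depends on where a sphere sits; and
OSEM reconstruction is non-linear, so a sphere's recovery depends on
its neighbors.  The same phantom filled the same way can therefore give
different RCs depending only on *which sphere is screwed into which
position* — 6! = 720 possible arrangements.  `spectrc` quantifies that
spread end-to-end: it voxelizes every arrangement of the PET-variant
(10–37 mm spheres) and SPECT-variant (13–60 mm, for Lu-177
harmonization) phantoms, simulates projections with an analytic
distance-dependent-PSF forward model (attenuation, TEW-consistent
scatter, Poisson noise at protocol count levels), reconstructs with
OSEM with and without resolution modeling (RR), and reports RC
statistics, recovery-curve fit ensembles, and PVC consequences.

## Model summary

* Forward model per view: sparse mass-preserving rotation into the
  detector frame, Beer–Lambert attenuation through the rotated μ-map,
  per-plane Gaussian blur with FWHM(D) = √(FWHM₀² + (αD)²), depth sum.
  The backprojector is the exact transpose.
* Scatter: effective broad-kernel component constructed so the
  triple-energy-window (TEW) estimate recovers it without bias.
* Reconstruction: OSEM, 10 subsets; `noRR` (attenuation only, analyzed
  at 50 updates) and `RR` (PSF modeled, analyzed at 200 updates).
* Recovery: RC = Σ(activity × occupancy) · v / (c · V_sphere) on a
  high-resolution mask grid; spread ϑ_RC = (RC_max − RC_min)/mean RC.
* Recovery curve: f_RC(d) = (1 + (β/d)^γ)⁻¹, fitted per arrangement
  (d and β in cm); PVC factor = 1 / f_RC(d).
* Agreement between curve sets: δ(d) = mean |RC_ref − RC_test|,
  Δ(d) = mean |RC_ref − mean ref| over matched configurations.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example: two sites, one lesion, different answers

Two sites measure the same phantom with identical protocols but
different sphere arrangements (`Standard` vs `Standard_120`), fit their
recovery curves, and correct a 10 mL (d = 2.67 cm) spherical lesion:

```bash
$ spectrc pvc-example
{
  "lesion_diameter_cm": 2.67,
  "sites": {
    "Site A": { "beta": 1.37, "gamma": 2.44, "rc": 0.84, "pvc_factor": 1.19, ... },
    "Site B": { "beta": 1.27, "gamma": 3.21, "rc": 0.92, "pvc_factor": 1.09, ... }
  },
  "percent_difference": 9.2
}
```

Site A reads RC = 0.84 off its curve and multiplies the lesion activity
by 1.19; Site B reads 0.92 and multiplies by 1.09.  The corrected
activity — and any dose derived from it — differs by 9.2 % purely
because of how the spheres were arranged during calibration.

## Running a sweep

```python
from spectrc import SweepConfig, run_sweep, permutation_stats

records = run_sweep(SweepConfig(master_seed=1))     # 24 structured arrangements
stats = permutation_stats(records)
```

On the desk preset (NEMA SPECT phantom, 2 × 60 views, 4.8 mm
reconstruction voxels, ~7 min on one core) the sweep reproduces the
structural findings of the full 720-arrangement campaign: the RC spread
ϑ_RC falls from ≈35 % (13 mm sphere) to ≈3 % (60 mm) without
resolution modeling and is uniformly smaller with it; resolution
modeling raises every mean RC; without it the best-recovering position
is always the top of the phantom, where the auto-contoured detector
comes closest; and noRR recoveries plateau (<1 % change) between 50 and
100 updates while the smallest sphere under RR is still converging at
200.  The CLI mirrors the library: `spectrc sweep`, `spectrc fit`,
`spectrc compare`, `spectrc pvc-example`.

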