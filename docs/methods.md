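# Methods

## Scope and conventions

The package analyzes 2D/3D multi-channel fluorescence stacks of calibration
beads. All lengths are nanometers internally; exported tables are µm. Arrays
are indexed `(channel, z, y, x)`; voxel boxes are half-open `[lo, hi)`; the
physical coordinate of voxel index `i` is `(i + 0.5) · pitch` (center-of-voxel
convention). Channel order follows file order; per-channel emission
wavelengths label the channels. Only TIFF-family input is read (OME-TIFF
with `PhysicalSize*` and Channel metadata, plain multi-page TIFF as a single
channel with user-supplied pixel sizes); vendor formats should be converted
to OME-TIFF first.

## Detection

Candidates are connected components of `{voxel ≥ T}` with 26-connectivity
(8-connectivity in a single plane): beads are compact blobs, and stricter
connectivity splits diagonal neighbors. The tight component box is padded by
`round(b · extent)` voxels per side per dimension, at least 1 (default
`b = 0.3`). Components whose padded box is clipped by the image or ROI
border are flagged and, by default, excluded from statistics — their tails
are unmeasurable. Size filtering keeps components whose largest lateral
extent lies within a pixel range; overlap exclusion removes *both* members
of every pair of intersecting padded boxes, evaluated on the original set so
the outcome is order-independent.

`auto_threshold` is this package's headless replacement for interactive
thresholding: Otsu's rule, re-applied to the super-threshold tail while the
foreground fraction exceeds 10%. The recursion matters because bead fields
are extremely foreground-sparse (often < 0.5% of voxels), a regime where a
single Otsu pass can split the background mode instead of isolating the
spots; when the first split is already sparse the recursion is a no-op.
Multi-thresholding commits detections pass by pass; at later (lower)
thresholds, components overlapping an already-committed core are suppressed
rather than re-detected, so bright beads do not reappear as rings of tails
around their committed boxes.

## Gaussian fitting

Each particle is fit over its padded box by least squares with
`I(v) = B + A·exp(−½ (v−c)ᵀRᵀ diag(1/σ²) R (v−c))`. Rotation uses intrinsic
Euler angles applied z-y-x (`R = Rz·Ry·Rx`); only θz exists for 2D fits.
Calibration beads are axisymmetric, so angle fitting is off by default and
θ = 0 is reported; with angles enabled, a laterally circular fit
(σx ≈ σy) reports θ = 0 since orientation is then undefined. A 2D fit on a
3D stack runs on the best-focus plane (maximum in-plane integrated
intensity; ties break to the lower index).

Initialization: center at the background-subtracted intensity centroid of
the tight box, σ at a quarter of the tight extent, base at the box-edge
median, peak at max − base. The optimizer (trust-region reflective, bounded)
keeps the center inside the padded box; failures after two jittered restarts
or degenerate (flat) input are flagged and the particle is dropped, with the
removal logged. The fit always runs on raw intensities — the local
background enters through the intensity correction, never by pre-subtracting
voxels (which would clip negatives). The reported residual
`ResNorm = SSR/(N·A²)` is dimensionless and comparable across SNR.

Localization precision under the standard conditions below is ~0.5 nm
laterally and ~1.2 nm axially per bead (3D RMSE ≈ 1.4 nm), consistent with
an information-theoretic (Cramér–Rao) estimate for the same model, grid, and
noise; the noiseless rendering/fitting bias is ≲ 0.2 nm.

## Local background and intensities

The background shell is the measurement box enlarged by a fraction `p` per
dimension (default 0.15; `p = 1` doubles every extent), minus the box itself
and minus any voxel belonging to another particle's box — the exception
handling that keeps close neighbors from contaminating the estimate. The
estimator is the median (robust to residual tails; mean available via
configuration). An empty shell (crowding, borders) falls back to the fitted
Gaussian base, flagged. Integrated intensity is the padded-box sum minus
`N·B`; maximum intensity is the largest raw voxel in the tight box. The
corrected integrated intensity is invariant (< 0.5%) to adding any constant
offset to the image.

## FWHM estimators

Axis profiles are sampled by trilinear interpolation along axis-parallel
lines through the *fitted* center at native pitch — resampled lines rather
than raw voxel rows, so the measurement does not depend on the center
falling on the grid. The half level is half the profile's own maximum (not
the fitted peak), which keeps tFWHM free of the fit. tFWHM locates the
crossings by linear interpolation between the bracketing native samples;
iFWHM resamples the profile 10-fold with a natural cubic spline first (the
factor is a configuration knob; the exact interpolation scheme is this
package's choice). gFWHM is `2√(2 ln 2)·σ`. FWHM is measured along the image
axes X/Y/Z, not principal axes, matching the per-axis output columns.

Estimator behavior on noiseless model data: with ≥ 3 samples per σ all three
agree within 2% (spline within 1%); the raw crossing carries a
sampling-phase error that grows to ~2.5% at 2.3 samples per σ and ~11 nm in
the axial regime (σz ≈ 200 nm at a 100 nm z-step), where the spline stays
sub-nanometer — the quantitative basis for recommending tFWHM laterally and
iFWHM axially. Lateral summary size is the mean of tFWHM X and Y over beads;
axial size is the mean iFWHM Z.

## Chromatic aberration

Matching is mutual nearest neighbor between the reference channel (default:
first; configurable) and every other channel within a 500 nm default radius
(typical chromatic shifts are far below bead spacing in a well-prepared
field). Beads unmatched in any channel are removed from all channels —
only complete rows can contribute offsets. Aberration per channel is the
per-bead `center_c − center_ref` with 2D/3D distances, averaged over beads;
export is in µm.

Calibrations: a full 3D affine transform (12 parameters, least squares,
needs ≥ 4 beads) or per-axis polynomial surfaces of the shift over lateral
field position (default degree 2 — axial shift varies slowly across the
field; the degree is a stated design choice). Applying a calibration maps
points directly; images are resampled trilinearly under the inverse map
(exact inverse for affine; for polynomial surfaces the shift is small and
slowly varying, so `p + shift(p)` serves as the inverse). Calibrations
round-trip through JSON and transfer between acquisitions on the same
optics.

## Field maps and flatness

Beads are binned by lateral center into an 8×8 half-open tile grid over the
field of view; per-tile means of intensity or FWHM expose vignetting and
off-axis degradation, exported as CSV + PNG. The flatness score,
`100 · min/max` over populated tile means, is this package's own summary
statistic — common practice inspects the surface plots without reducing
them to a number; it is scale-invariant and labeled as such in reports.

## Synthetic bead fields

The simulator emulates a multispectral bead slide: solid spheres of known
diameter, voxelized on a 4× supersampled grid with antialiased edge
coverage, convolved with per-channel anisotropic Gaussian PSFs, binned to
the native grid (a single-plane image is the in-focus central slice of the
3D blur). Placement is uniform with a minimum separation of 4× the lateral
PSF FWHM plus a bead diameter (an evenly distributed, non-aggregated
field), with margins keeping all tails inside the volume. Per-channel
chromatic shifts (constant vectors or field-position functions), a Gaussian
illumination vignette, Poisson shot noise (signal plus an optional uniform
background-fluorescence rate), Gaussian read noise, a camera offset, and
16-bit quantization complete the model. A fixed seed reproduces a stack bit
for bit.

PSF defaults use the standard Gaussian approximations: lateral FWHM
0.51 λ/NA and axial FWHM 0.88 λ/(n − √(n² − NA²)) with NA 1.4, n 1.515.
SNR is defined as the noiseless bead peak over the background noise SD
(`√(background_photons + read²)`), and the photon budget is derived from it.

What the simulator does *not* emulate: vectorial/aberrated PSFs (Airy rings,
spherical aberration, the widefield missing cone), sCMOS fixed-pattern
noise, pinhole crosstalk, bead polydispersity, and sample drift. Tests
passing on these fields therefore validate the estimators against an ideal
Gaussian-optics camera model, not against every artifact of real hardware.

## Validation experiments and standard conditions

All validation experiments (`speckler.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) use 65 nm lateral pitch,
100 nm z-step, and a photon-rich operating point: background fluorescence
400 photons/voxel, read noise 5, offset 100, SNR 100. The SNR guidance for
bead calibration is "at least 20–50, ideally more"; SNR 100 with a
shot-noise-limited background represents a well-exposed acquisition (peak
~2000 photons). A Cramér–Rao analysis shows why the operating point matters:
at SNR exactly 50 with a read-noise-only background, no estimator can
localize better than ~2.4 nm axially on this grid, whereas the photon-rich
SNR-100 regime supports the ~1.4 nm 3D RMSE the pipeline achieves.

Problem sizes: 200 beads for the localization and chromatic experiments
(fields of 640×640×26 voxels), 100 beads for the resolution experiment, 50
spheres for supra-PSF sizing — large enough for sub-nanometer standard
errors on the reported means while keeping a full run in minutes on one
core.

## Known limitations

- **Sphere sizing below ~5× the PSF.** The central-profile FWHM of a 3D
  sphere blurred by a PSF of comparable scale reads *below* the geometric
  diameter: unlike a 1D top-hat (whose FWHM survives any symmetric blur
  exactly — verified against a dense 1D convolution oracle), the transverse
  curvature of the ball erodes the profile near the equator. Two independent
  oracles (a semi-analytic 1D reduction and a 5 nm 3D grid) agree that a
  500 nm sphere under a 190 nm lateral / 470 nm axial FWHM PSF has a true
  central x-profile width of ~411 nm (−18%); even an unphysically sharp
  axial response leaves −5%. Recovery within 3% requires a PSF FWHM ≲ D/5,
  which the test suite verifies in that regime. The pipeline reports the
  faithful profile measurement and applies no sphere-deblurring correction
  (deliberately out of scope); users sizing beads not much larger than the
  PSF should expect this bias.
- **tFWHM sampling-phase error.** At fewer than ~3 samples per σ the raw
  crossing estimator acquires a positive bias up to a few percent; use
  iFWHM (or finer sampling) in that regime, as recommended above.
- **Otsu thresholds on unusual histograms.** The recursive rule targets
  sparse bright spots on a unimodal background; dense fields or strongly
  structured backgrounds may still need an explicit threshold.
- **Polynomial calibration surfaces** model the shift as a function of
  lateral position only; axial field dependence beyond that is not captured.
- **Matching** assumes bead spacing well above the chromatic shift; fields
  violating this (aggregated beads) lose beads to the mutual-NN criterion
  rather than producing wrong pairs.
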