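# Methods

This note documents what `petiq` computes, the conventions it fixes where
the field leaves room, and what its synthetic test bed does and does not
emulate.

## Image model and coordinates

A `Volume` is a (slice, row, column) grid of activity concentration
(kBq/ml) with isotropic in-plane pixel spacing `p` and uniform slice
spacing.  Voxel indices are 0-based; physical coordinates always refer to
**voxel centers**; in-plane axes map (row, column) → (y, x).  One stated
convention avoids the half-pixel errors that otherwise creep into ROI
placement and FWHM interpolation.  Values are used exactly as stored — no
decay correction is applied at read time, so all concentrations are
scan-time concentrations and any decay handling is the user's calibration
input.  Anisotropic in-plane spacing is rejected rather than resampled,
because the NPS estimator uses a single pixel size `p`.

## Digital phantoms

`generate_nema_phantom` rasterizes the NU-2 body phantom analytically: the
standard torso cross-section (147-mm half-disc over a 140×77-mm rectangle
with 77-mm corner rounds), six spheres (default inner diameters
10/13/17/22/28/37 mm) on a 57.2-mm ring, and a 50-mm cold lung insert —
all configurable.  Defaults follow the standard phantom: hot spheres at
40 kBq/ml and a background at one eighth of that (8:1); halving the ratio
to 4:1 means doubling the background.  Partial volume is handled by
midpoint supersampling (default 4 points per axis, i.e. 64 samples per
voxel); the resulting total activity matches the closed-form region volumes
to better than 0.1 %.  `supersample=1` degenerates to binary
center-in-region labeling, which is the configuration in which an
unblurred, noiseless phantom yields recovery coefficients of exactly 1 —
with partial-volume rasterization on, edge-voxel dilution makes sub-unity
RC the *correct* answer even for a perfect image.

Point sources are deposited by bilinear splatting, so the total deposited
signal equals the requested amplitude at any sub-pixel position.  On an
odd-sized matrix the central nominal position falls exactly on a voxel
center and the splat is a single voxel; at a half-pixel offset the splat
footprint adds `δ(1−δ)p²` of variance per axis to any subsequent blur,
which the resolution tests account for in quadrature.

Imaging physics is deliberately reduced to two stages:

1. **System PSF** — 2-D in-plane Gaussian convolution of stated FWHM.
2. **Noise** — zero-mean Gaussian with SD proportional to the local
   noiseless signal (`amplitude × mean`), optionally shaped by smoothing
   the *noise field* with a Gaussian of stated correlation FWHM and
   rescaling so variance is preserved.  Correlation therefore changes noise
   texture, never noise magnitude.  Noise is Gaussian rather than Poisson
   on counts because the analysis operates on reconstructed activity
   images, where noise is approximately Gaussian and spatially correlated;
   this also keeps the ground-truth spectrum analytic.

Reconstruction conditions (NC / RM / TOF / RM+TOF) are opaque presets of
(PSF width, noise amplitude, noise correlation).  The shipped defaults
encode the qualitative ordering such studies report — resolution modeling
narrows the PSF (8.52–8.55 mm vs 9.31–9.36 mm point-source widths) and
pushes noise power toward low frequencies; time-of-flight lowers the noise
amplitude; the uncorrected condition has the largest total noise — and are
**not** calibrated to any published noise table.  Nothing downstream
branches on a label's meaning; all condition differences enter through the
presets.

What the generator does *not* emulate: sinogram/projection physics,
iterative-reconstruction nonstationarity (noise here is stationary within
the phantom), TOF kernels, scatter/attenuation, or continuous bed motion.
Passing tests demonstrate the estimators are correct on images whose truth
is known; they do not certify scanner-specific behavior such as
RM edge ringing or noise nonstationarity near the phantom boundary.

## ROI layout and pose

`locate_phantom` finds the phantom by normalized cross-correlation of a
sphere-ring template (+1 in the sphere discs, −1 in the lung insert)
against the highest-contrast slice, searching rotations in 0.5° steps over
±15° with ties broken toward the smallest rotation magnitude and a
parabolic sub-pixel peak refinement.  Windows essentially devoid of signal
are excluded (empty windows make normalized correlation numerically
meaningless).  A supplied pose always wins over the search — synthetic
studies use the exact generator pose.  Below a correlation of 0.3 the
search fails loudly and asks for a manual pose.

The ROI layout follows the NU-2 template: hot ROIs matched in physical
diameter and centered on the spheres; twelve background locations, each
carrying one concentric circular ROI per sphere size class (six classes —
the 37-mm ROI plus the five smaller ones it contains); sixty 9×9-pixel
square ROIs for the NPS at the same twelve locations on five slices (the
sphere-center plane and ±10/±20 mm, matching the slices used for
background variability).  The shipped twelve locations keep every ROI
≥ 15 mm from the phantom boundary, clear of all spheres and the lung
insert, and non-overlapping; they are a configuration table, editable per
site.  A voxel belongs to a circular ROI iff its center is strictly inside
the circle (no fractional weighting) — simple, testable by brute-force
counting, and consistent with common QC software.  Square ROIs snap to the
nearest voxel center to avoid interpolating noise fields.

## Contrast metrics

`B_measured,j` is the unweighted mean of the twelve size-j background ROI
means (the NU-2 "global mean" convention), not a voxel-pooled mean.  The
CNR noise term `σ_bg,j^37` is the **population** SD of the 37-mm ROI at
location j, whatever the sphere size being scored; using the large ROI
stabilizes the noise estimate, and population (rather than sample) SD
matches the variance convention of the NPS.  RC values above 1 are
reported as-is (overshoot from resolution-modeling ringing is signal, not
error).  RC with `H_true = B_true` is refused explicitly.

## Noise-power spectrum

Each 9×9 patch is mean-subtracted, zero-padded to 64×64, transformed, and
scaled by `p²/N_s²` with `N_s = 9` — the *data* extent, not the padded
length.  With this convention the white-noise Parseval identity holds
exactly and padding is purely interpolative (integrated power is invariant
to the padding length); `N_s` remains configurable for sensitivity checks.
The 60 patch spectra are averaged, binned radially in steps of `1/(64p)`
up to Nyquist, divided by the squared background concentration (making the
curve mm² and its AUC mm; a literal first-power normalization is available
behind `normalization_power=1`), and integrated trapezoidally from the
first bin.  The DC bin is excluded — after mean subtraction it carries no
noise.  No detrending beyond mean subtraction is applied.

One estimator property worth knowing: mean subtraction suppresses power
*below* the patch fundamental `1/(9p)`, because padded-grid bins near DC
interpolate between the zeroed DC coefficient and the first data
frequency.  White-noise flatness therefore holds from `1/(9p)` upward
(`NPSResult.first_data_frequency`), and the suppressed low bins are part of
the estimator's expected behavior, not a defect.

## Spatial resolution

Profiles are raw voxel rows/columns through the peak voxel — the image is
never interpolated.  The peak is located (and its height estimated) by a
parabolic fit through the maximum sample and its neighbors; each
half-maximum crossing is found by linear interpolation between the
bracketing samples.  Bias stays below a quarter pixel across sub-pixel
source positions.

The MTF normalizes the 50×50 mm ROI by its integral (so MTF(0) = 1) and
uses the transform **magnitude**, making it invariant to the sub-pixel
phase of the source position.  The 1-D curve averages the two
zero-frequency lines with their +f and −f halves folded.  The normalized
ROI is zero-padded (default 1024) before the FFT: this interpolates the
spectrum exactly as the NPS patches are padded, shrinking the frequency
step from ≈0.02 to ≈0.0006 mm⁻¹ so the linearly interpolated MTF = 0.1
crossing (the limiting resolution) carries no visible grid bias on a
convex curve.  No background is subtracted by default (sources are in
air); a tail-mean subtraction exists for noisy inputs.

## Statistics

Condition panels are DataFrames (replicates × conditions).  Friedman uses
the chi-square approximation with average ranks on ties; with only three
replicate scans the approximation is coarse (and conservative in the
simulated null), so an exhaustive-permutation p-value is available for
small designs.  Dunn's post hoc uses
`z = ΔR̄ / sqrt(k(k+1)/(6n))` with Holm adjustment by default
(Bonferroni and none are selectable — no adjustment is named in common
write-ups, so the choice is explicit configuration).  MTF curves are
compared by Tukey's HSD treating every frequency sample as an independent
observation; the within-curve correlation of adjacent frequencies is
deliberately not modeled, and p-values for curves should be read
accordingly.  Paired t-tests handle the zero-variance degenerate case by
reporting ±inf with an underflow-safe minimum p instead of NaN.  α = 0.05
throughout, echoed in the findings table.

## Pipeline determinism and scale

Every stochastic step derives its seed from the config's `base_seed`
(per-condition, per-scan offsets), so a config determines all CSV outputs
byte-for-byte; the manifest stores the config, its SHA-256 and per-artifact
hashes, and `verify_manifest` flags any tampering.  The demo-scale study
(4 conditions × 3 NEMA scans at 200×200×25, plus 2 point-source repeats at
513×513) runs in a few seconds on one CPU; tests use reduced grids
(128×128×13 pipelines, 2-mm pixels for the convolution-oracle comparison,
1-mm pixels for the fine-blur recovery property) chosen so each check's
reference — a closed form, a continuum convolution, or a Monte-Carlo
estimate — is valid at the stated tolerance.  In particular, the
blurred-RC oracle comparison runs on a 2-mm grid because applying the blur
*after* rasterization (what any voxel-domain simulator does) deviates from
the continuum convolution by a few percent for the smallest sphere when
the PSF σ is only ≈1 pixel; on the finer grid the discrete and continuum
answers agree and the oracle is meaningful.

## Known limitations

- 2-D (in-plane) NPS and PSF only; no 3-D NPS, no axial FWHM, no
  off-center resolution analysis.
- Single-scan spatial NPS (ROI-based), not ensemble NPS over repeated
  acquisitions.
- The noise model is stationary within the phantom and Gaussian; real
  iterative reconstructions produce object-dependent, nonstationary noise.
- No SUV computation, registration, or resampling; volumes are consumed at
  their native grid.
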