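# petiq — quantitative PET image-quality analysis

`petiq` measures how reconstruction choices (time-of-flight, resolution
modeling, filters, iteration counts) change PET image quality, using the two
standard QC acquisitions a clinical physicist already has: the NEMA NU-2
image-quality body phantom and point sources in air.  It computes, per
reconstruction condition:

- **Recovery coefficients** per hot sphere *j*:
  `RC_j = (H_meas,j − B_meas,j) / (H_true − B_true)`, with `B_meas,j` the
  global mean of the twelve size-matched background ROIs.
- **Contrast-to-noise ratio** per sphere *i*:
  `CNR_i = (1/12) Σ_j (S_hot^i − S_bg,j^i) / σ_bg,j^37` — size-matched
  background means, but the 37-mm ROI's SD as the noise term.
- **Noise-power spectrum** from sixty mean-subtracted 9×9 background
  patches on five slices, `NPS_k = (p²/N_s²) |FT(R_k − R̄_k)|²`,
  zero-padded to 64×64, radially binned, normalized by the squared
  background activity concentration, and integrated to a scalar **AUC**
  (mm) summarizing total noise.
- **MTF** as the normalized magnitude spectrum of a 50×50 mm point-source
  ROI (1-D curve = average along the two zero-frequency lines), with the
  **limiting resolution** read off at MTF = 0.1.
- **FWHM** of radial/tangential line profiles through each point source
  (parabolic peak fit, linear half-maximum interpolation).
- A **statistics layer** for condition comparisons: Friedman test with
  Dunn's post hoc, Tukey's HSD across MTF frequency points, paired t-tests
  on FWHM.

Because scanner time is scarce, the package also ships a **digital phantom
generator** — a NEMA body phantom and point sources with exactly known
ground truth, imaged through a Gaussian system PSF with optionally
correlated, signal-proportional noise — so every metric can be validated
end-to-end without any scanner data.

## Worked example

```sh
python examples/04_mtf_and_fwhm.py
```

```
with resolution modeling (PSF 8.55 mm):
  FWHM radial 8.58 mm, tangential 8.58 mm
  limiting resolution (MTF = 0.1): 0.094 mm^-1
without resolution modeling (PSF 9.36 mm):
  FWHM radial 9.36 mm, tangential 9.36 mm
  limiting resolution (MTF = 0.1): 0.086 mm^-1
```

The narrower resolution-modeled PSF buys back roughly 0.8 mm of
point-source width and raises the limiting resolution from 0.086 to
0.094 mm⁻¹ — i.e. finer detail survives the reconstruction.  The other
examples (`examples/01…05`) walk through phantom simulation, RC/CNR, the
NPS, and a complete four-condition study with statistics; `05` finds the
pattern a scanner study shows: resolution modeling shifts FWHM decisively
(paired-t p < 1e-5) while RC differences between conditions mostly stay
non-significant at three replicate scans.

A thin CLI wraps the same library calls:

```sh
petiq full --config examples/demo_config.yaml --out study_output
petiq report --results-dir study_output
petiq verify --results-dir study_output     # manifest/integrity check
```

All outputs are CSV tables plus a manifest with config and artifact hashes;
identical configs (seeds included) reproduce identical bytes.

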