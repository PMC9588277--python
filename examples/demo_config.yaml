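# Demo study configuration: four reconstruction-condition presets,
# three replicate NEMA scans, two point-source repeats.
# Run:  petiq full --config examples/demo_config.yaml --out study_output
conditions:
- label: NC
  psf_fwhm: 9.36
  noise_amplitude: 0.1
  noise_correlation_fwhm: 6.0
- label: TOF
  psf_fwhm: 9.31
  noise_amplitude: 0.08
  noise_correlation_fwhm: 6.0
- label: RM
  psf_fwhm: 8.52
  noise_amplitude: 0.082
  noise_correlation_fwhm: 8.5
- label: RM+TOF
  psf_fwhm: 8.55
  noise_amplitude: 0.075
  noise_correlation_fwhm: 7.5
h_true: 40.0
b_true: 5.0
n_scans: 3
base_seed: 1
matrix_size: 200
pixel_spacing: 4.07
slice_spacing: 5.0
n_slices: 25
ps_matrix: 513
ps_pixel_spacing: 1.59
ps_positions:
- - 0.0
  - 0.0
- - 70.0
  - 0.0
- - 0.0
  - 70.0
ps_amplitude: 1000.0
n_resolution_repeats: 2
nps_normalization_power: 2
dunn_adjust: holm
alpha: 0.05
fwhm_pairs:
- - RM
  - NC
- - RM+TOF
  - TOF
- - TOF
  - NC
- - RM+TOF
  - RM
volume_paths: null
figures: false
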