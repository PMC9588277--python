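"""Point-source spatial resolution: FWHM, MTF and limiting resolution.

Images a point source through two system PSFs typical of reconstructions
with and without resolution modeling, and prints the FWHM of the line
profiles plus the frequency where the MTF drops to 0.1.
"""

import petiq as pq

for label, fwhm in (("with resolution modeling", 8.55),
                    ("without resolution modeling", 9.36)):
    vol = pq.generate_point_sources([(0.0, 0.0)], amplitude=1000.0,
                                    matrix_size=513, pixel_spacing=1.59)
    vol = pq.apply_system_blur(vol, fwhm)
    radial = pq.profile_fwhm(vol, (0.0, 0.0), "radial")
    tangential = pq.profile_fwhm(vol, (0.0, 0.0), "tangential")
    mtf = pq.mtf_from_point_source(vol, (0.0, 0.0))
    print(f"{label} (PSF {fwhm} mm):")
    print(f"  FWHM radial {radial.fwhm:.2f} mm, "
          f"tangential {tangential.fwhm:.2f} mm")
    print(f"  limiting resolution (MTF = 0.1): "
          f"{mtf.limiting_resolution:.3f} mm^-1")
# The narrower PSF recovers ~0.8 mm of width and pushes the limiting
# resolution from 0.086 to 0.094 mm^-1 — higher frequency = finer detail.
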