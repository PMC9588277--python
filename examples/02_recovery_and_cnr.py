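"""Recovery coefficients and CNR from a simulated NEMA scan.

Simulates one noisy scan, finds the phantom automatically, places the NU-2
ROI layout and prints RC and CNR per sphere.  RC near 1 means the sphere's
true contrast is fully recovered; blur drags small spheres far below 1.
"""

import petiq as pq

truth = pq.PhantomTruth(h_true=40.0, b_true=5.0, seed=2)
vol, truth = pq.generate_nema_phantom(truth)
preset = pq.DEFAULT_PRESETS["RM+TOF"]
vol = pq.add_noise(pq.apply_system_blur(vol, preset.psf_fwhm), preset, seed=2)

pose = pq.locate_phantom(vol)
print(f"phantom found at ({pose.center_y_mm:+.1f}, {pose.center_x_mm:+.1f}) mm, "
      f"rotation {pose.rotation_deg:+.1f} deg, correlation {pose.score:.2f}")

rois = pq.place_nema_rois(vol, pose)
rc = pq.recovery_coefficients(vol, rois, truth.h_true, truth.b_true)
cnr = pq.contrast_to_noise(vol, rois)

print(f"{'sphere':>8} {'RC':>7} {'CNR':>8}")
for (_, r), (_, c) in zip(rc.table.iterrows(), cnr.table.iterrows()):
    print(f"{r.sphere_mm:>6.0f}mm {r.RC:>7.3f} {c.CNR:>8.2f}")
# RC rises with sphere diameter (less partial-volume loss); CNR divides the
# same contrast by the 37-mm background-ROI SD, so it tracks detectability.
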