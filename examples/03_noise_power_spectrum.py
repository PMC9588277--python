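"""Noise-power spectrum and AUC from the 60 background ROIs.

Compares white noise with spatially correlated noise of identical variance:
the NPS AUC (total noise) stays similar while the spectrum shifts toward
low frequencies — the signature the NPS is designed to expose and a plain
variance number would miss.
"""

import numpy as np

import petiq as pq

vol, truth = pq.generate_nema_phantom(pq.PhantomTruth(seed=3))
pose = pq.PhantomPose(0.0, 0.0, vol.n_slices // 2, 0.0)
rois = pq.place_nema_rois(vol, pose)

white = pq.add_noise(vol, pq.ConditionPreset("white", 0, 0.05, 0.0), seed=3)
corr = pq.add_noise(vol, pq.ConditionPreset("correlated", 0, 0.05, 8.0), seed=3)

for label, noisy in (("white", white), ("correlated (8 mm)", corr)):
    res = pq.volume_nps(noisy, rois, truth.b_true)
    lo = res.radial_freqs < res.radial_freqs[-1] / 3
    frac = np.trapezoid(res.nps1d[lo], res.radial_freqs[lo]) / res.auc
    print(f"{label:>18}: AUC = {res.auc:.4f} mm, "
          f"peak at {res.peak_frequency:.3f} mm^-1, "
          f"{100 * frac:.0f}% of power below f_Nyq/3")
# Equal noise magnitude, very different texture: the correlated field piles
# most of its power into the lowest-frequency third of the spectrum.
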