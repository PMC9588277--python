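"""Recovery coefficients and contrast-to-noise ratios.

For hot sphere j with measured ROI mean H_meas,j and B_meas,j the global
(unweighted) mean of the twelve size-j background ROI means,

    RC_j = (H_meas,j - B_meas,j) / (H_true - B_true),

so an RC of 1 means perfect quantitation; no truncation is applied above 1
(overshoot from resolution-modeling ringing is real signal).

CNR for sphere i averages twelve per-location ratios

    CNR_i = (1/12) * sum_j (S_hot_i - S_bg,j_i) / sigma_bg,j_37,

where S_bg,j_i is the size-i background mean at location j and sigma_bg,j_37
is the population SD of the *37-mm* background ROI at that location — the
size-matched mean but the large-ROI SD, which stabilizes the noise estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .roi import ROISet, roi_statistics
from .volume import Volume

__all__ = ["RCResult", "CNRResult", "recovery_coefficients", "contrast_to_noise"]

_SD_REFERENCE_CLASS = 37.0


@dataclass
class RCResult:
    """Per-sphere recovery coefficients with their components."""

    table: pd.DataFrame  # sphere_mm, H_measured, B_measured, RC
    h_true: float
    b_true: float

    def rc(self, sphere_mm: float) -> float:
        row = self.table[self.table.sphere_mm == sphere_mm]
        if row.empty:
            raise KeyError(f"no sphere of diameter {sphere_mm} mm")
        return float(row.RC.iloc[0])


@dataclass
class CNRResult:
    """Per-sphere CNR with the twelve per-location terms retained."""

    table: pd.DataFrame      # sphere_mm, S_hot, CNR
    per_location: pd.DataFrame  # sphere_mm, location, S_bg, sigma_37, term
    n_background: int = 12

    def cnr(self, sphere_mm: float) -> float:
        row = self.table[self.table.sphere_mm == sphere_mm]
        if row.empty:
            raise KeyError(f"no sphere of diameter {sphere_mm} mm")
        return float(row.CNR.iloc[0])


def recovery_coefficients(volume: Volume, roiset: ROISet,
                          h_true: float, b_true: float) -> RCResult:
    """Recovery coefficient for every hot sphere in ``roiset``."""
    if h_true == b_true:
        raise AnalysisError(
            "H_true equals B_true: recovery coefficient denominator is zero"
        )
    rows = []
    for hot in roiset.hot_rois:
        size = float(hot.size_class_mm)
        h_meas = roi_statistics(volume, hot)[0]
        bg = roiset.background_rois[size]
        b_meas = float(np.mean([roi_statistics(volume, r)[0] for r in bg]))
        rc = (h_meas - b_meas) / (h_true - b_true)
        rows.append((size, h_meas, b_meas, rc))
    table = pd.DataFrame(rows, columns=["sphere_mm", "H_measured",
                                        "B_measured", "RC"])
    return RCResult(table.sort_values("sphere_mm", ignore_index=True),
                    h_true, b_true)


def contrast_to_noise(volume: Volume, roiset: ROISet) -> CNRResult:
    """Net CNR per hot sphere, averaged over the twelve background locations."""
    if _SD_REFERENCE_CLASS not in roiset.background_rois:
        raise AnalysisError("ROI set lacks the 37-mm background class needed "
                            "for the CNR noise term")
    sigma_by_location = {}
    for r in roiset.background_rois[_SD_REFERENCE_CLASS]:
        sd = roi_statistics(volume, r)[1]
        if sd == 0:
            raise AnalysisError(
                f"background ROI {r.location} (37 mm) has zero SD — "
                "a noiseless image cannot yield a CNR"
            )
        sigma_by_location[r.location] = sd

    rows, detail = [], []
    for hot in roiset.hot_rois:
        size = float(hot.size_class_mm)
        s_hot = roi_statistics(volume, hot)[0]
        terms = []
        for r in roiset.background_rois[size]:
            s_bg = roi_statistics(volume, r)[0]
            sigma = sigma_by_location[r.location]
            term = (s_hot - s_bg) / sigma
            terms.append(term)
            detail.append((size, r.location, s_bg, sigma, term))
        rows.append((size, s_hot, float(np.mean(terms))))
    table = pd.DataFrame(rows, columns=["sphere_mm", "S_hot", "CNR"])
    per_location = pd.DataFrame(
        detail, columns=["sphere_mm", "location", "S_bg", "sigma_37", "term"])
    return CNRResult(table.sort_values("sphere_mm", ignore_index=True),
                     per_location)
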