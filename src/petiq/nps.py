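"""Noise-power spectrum from background patches.

Each 9x9 background patch R_k is mean-subtracted, zero-padded to 64x64 and
Fourier transformed; the two-dimensional NPS of patch k is

    NPS_k(s_x, s_y) = (p^2 / N_s^2) |FT(R_k - mean(R_k))|^2,

with p the pixel size (mm) and N_s = 9 the *data* extent.  With that
normalization the white-noise Parseval identity holds exactly and
zero-padding is purely interpolative (the spectrum does not depend on the
padding length); N_s is configurable for sensitivity checks.  The image NPS
averages the 60 patch spectra, is binned radially in one padded-grid
frequency step 1/(64 p), divided by the background activity concentration
squared (units mm^2, so the AUC carries mm), and integrated trapezoidally
from the first bin to Nyquist.  The DC bin is excluded: after mean
subtraction it carries no noise.

Mean subtraction also suppresses power *below* the patch fundamental
frequency 1/(9 p): padded-grid bins near DC interpolate between the zeroed
DC coefficient and the first data frequency.  White-noise flatness therefore
only holds from 1/(9 p) upward; see ``first_data_frequency``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .roi import ROISet, extract_patch
from .volume import Volume

__all__ = ["NoisePatch", "NPSResult", "patch_nps", "volume_nps", "nps_auc"]


@dataclass
class NoisePatch:
    """One square background patch (kBq/ml values) with its pixel size."""

    values: np.ndarray
    pixel_size: float
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise AnalysisError(f"patch must be square, got {self.values.shape}")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class NPSResult:
    nps2d: np.ndarray          # padded-grid 2-D NPS, mm^2 (kBq/ml)^2, patch avg
    radial_freqs: np.ndarray   # bin centers, mm^-1, (0, Nyquist]
    nps1d: np.ndarray          # normalized radial NPS, mm^2
    normalization: float       # background concentration used (kBq/ml)
    auc: float                 # mm
    n_patches: int
    ns: int                    # transform normalization length
    pixel_size: float

    @property
    def peak_frequency(self) -> float:
        return float(self.radial_freqs[int(np.argmax(self.nps1d))])

    @property
    def first_data_frequency(self) -> float:
        """Patch fundamental 1/(N_s p); flatness holds from here upward."""
        return 1.0 / (self.ns * self.pixel_size)


def patch_nps(patch: NoisePatch, pad_to: int = 64, ns: int | None = None) -> np.ndarray:
    """2-D noise power of one patch on the (padded) frequency grid."""
    n = patch.values.shape[0]
    if pad_to < n:
        raise AnalysisError(f"pad_to={pad_to} smaller than patch size {n}")
    ns = n if ns is None else ns
    residual = patch.values - patch.values.mean()
    padded = np.zeros((pad_to, pad_to))
    padded[:n, :n] = residual
    ft = np.fft.fft2(padded)
    return (patch.pixel_size**2 / ns**2) * np.abs(ft) ** 2


def volume_nps(
    volume: Volume,
    roiset: ROISet,
    background_concentration: float,
    pad_to: int = 64,
    ns: int | None = None,
    normalization_power: int = 2,
    bin_width: float | None = None,
) -> NPSResult:
    """Image NPS averaged over the 60 square background ROIs.

    ``normalization_power`` of 2 (default) divides the spectrum by the
    background concentration squared so AUC carries units of mm; 1 is the
    literal first-power normalization, retained behind this switch.
    """
    if len(roiset.nps_rois) < 60:
        missing = 60 - len(roiset.nps_rois)
        raise AnalysisError(f"need 60 NPS ROIs, {missing} missing")
    if background_concentration <= 0:
        raise AnalysisError("background concentration must be positive")

    p = volume.pixel_spacing
    patches = [
        NoisePatch(extract_patch(volume, roi), p,
                   roi_id=f"loc{roi.location}@slice{roi.slice.slice_index}")
        for roi in roiset.nps_rois
    ]
    ns_eff = ns if ns is not None else patches[0].values.shape[0]
    nps2d = np.mean([patch_nps(pt, pad_to, ns_eff) for pt in patches], axis=0)

    freqs = np.fft.fftfreq(pad_to, d=p)
    fr = np.hypot(freqs[:, None], freqs[None, :])
    nyquist = 1.0 / (2.0 * p)
    bw = bin_width if bin_width is not None else 1.0 / (pad_to * p)
    n_bins = int(round(nyquist / bw))
    centers = (np.arange(n_bins) + 1) * bw
    idx = np.round(fr / bw).astype(int)  # 0 = DC bin (excluded)
    norm = float(background_concentration) ** normalization_power
    nps1d = np.empty(n_bins)
    for b in range(1, n_bins + 1):
        sel = idx == b
        if not sel.any():
            nps1d[b - 1] = np.nan
            continue
        nps1d[b - 1] = nps2d[sel].mean() / norm
    valid = ~np.isnan(nps1d)
    centers, nps1d = centers[valid], nps1d[valid]

    result = NPSResult(nps2d, centers, nps1d, float(background_concentration),
                       auc=0.0, n_patches=len(patches), ns=ns_eff, pixel_size=p)
    result.auc = nps_auc(result)
    return result


def nps_auc(result: NPSResult) -> float:
    """Trapezoidal integral of the radial NPS from the first bin to Nyquist."""
    if result.nps1d.size == 0:
        raise AnalysisError("empty radial NPS")
    if result.nps1d.size == 1:
        return 0.0
    return float(np.trapezoid(result.nps1d, result.radial_freqs))
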