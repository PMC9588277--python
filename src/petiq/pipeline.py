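"""End-to-end study orchestration.

A :class:`RunConfig` fully determines a study: which reconstruction
conditions (as opaque presets — the pipeline never branches on what RM or
TOF "mean"), how many replicate scans, the phantom truth, all analysis
switches, and every seed.  Identical configs produce byte-identical CSV
outputs.  CSV tables are the canonical artifacts; figures are optional.

Stages
------
``run_nema_analysis``       phantom scans -> RC / CNR / NPS tables
``run_resolution_analysis`` point sources -> FWHM / MTF / limiting resolution
``run_full_study``          both + the statistical findings table + manifest
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .contrast import contrast_to_noise, recovery_coefficients
from .errors import AnalysisError, ConfigError, DataError
from .nps import volume_nps
from .phantom import (DEFAULT_PRESETS, ConditionPreset, PhantomTruth,
                      add_noise, apply_system_blur, generate_nema_phantom,
                      generate_point_sources)
from .resolution import mtf_from_point_source, profile_fwhm
from .roi import locate_phantom, place_nema_rois
from .stats import curve_difference_test, dunn_posthoc, friedman_test, paired_t
from .volume import read_volume

log = logging.getLogger("petiq")

__all__ = ["RunConfig", "run_nema_analysis", "run_resolution_analysis",
           "run_full_study", "verify_manifest"]


@dataclass
class RunConfig:
    """Complete, seed-explicit description of one study."""

    conditions: list[ConditionPreset] = field(
        default_factory=lambda: list(DEFAULT_PRESETS.values()))
    h_true: float = 40.0
    b_true: float = 5.0                      # 8:1 by default
    n_scans: int = 3
    base_seed: int = 1
    # NEMA grid
    matrix_size: int = 200
    pixel_spacing: float = 4.07
    slice_spacing: float = 5.0
    n_slices: int = 25
    # point sources
    ps_matrix: int = 513
    ps_pixel_spacing: float = 1.59
    ps_positions: tuple = ((0.0, 0.0), (70.0, 0.0), (0.0, 70.0))
    ps_amplitude: float = 1000.0
    n_resolution_repeats: int = 2
    # analysis switches
    nps_normalization_power: int = 2
    dunn_adjust: str = "holm"
    alpha: float = 0.05
    fwhm_pairs: tuple = (("RM", "NC"), ("RM+TOF", "TOF"),
                         ("TOF", "NC"), ("RM+TOF", "RM"))
    # inputs: None -> simulate; else {condition label: [volume paths]}
    volume_paths: dict | None = None
    figures: bool = False

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ConfigError("n_scans must be >= 1")
        if self.base_seed is None:
            raise ConfigError("a base seed is mandatory: no hidden RNG state")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate condition labels in {labels}")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = [
                c if isinstance(c, ConditionPreset) else ConditionPreset(**c)
                for c in d["conditions"]
            ]
        if "ps_positions" in d:
            d["ps_positions"] = tuple(tuple(p) for p in d["ps_positions"])
        if "fwhm_pairs" in d:
            d["fwhm_pairs"] = tuple(tuple(p) for p in d["fwhm_pairs"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad config: {exc}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def scan_seed(self, condition_index: int, scan_index: int) -> int:
        return (self.base_seed + 104729 * condition_index + 7919 * scan_index) % (2**31)


def _log_stage(stage: str, t0: float, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s elapsed=%.2fs %s", stage, time.time() - t0, kv)


def _simulate_scan(config: RunConfig, preset: ConditionPreset, seed: int):
    truth = PhantomTruth(h_true=config.h_true, b_true=config.b_true,
                         psf_fwhm=preset.psf_fwhm, seed=seed,
                         noise_model={"amplitude": preset.noise_amplitude,
                                      "correlation_fwhm": preset.noise_correlation_fwhm})
    vol, truth = generate_nema_phantom(
        truth, matrix_size=config.matrix_size,
        pixel_spacing=config.pixel_spacing,
        slice_spacing=config.slice_spacing, n_slices=config.n_slices)
    vol = apply_system_blur(vol, preset.psf_fwhm)
    return add_noise(vol, preset, seed), truth


def run_nema_analysis(config: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-condition, per-scan RC / CNR / NPS tables.

    Conditions whose inputs are missing (load mode) are reported as explicit
    gaps rather than aborting the whole study.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rc_rows, cnr_rows, auc_rows, curve_rows, gaps = [], [], [], [], []

    for ci, preset in enumerate(config.conditions):
        roiset = None
        for si in range(config.n_scans):
            seed = config.scan_seed(ci, si)
            if config.volume_paths is None:
                vol, _ = _simulate_scan(config, preset, seed)
            else:
                paths = config.volume_paths.get(preset.label, [])
                if si >= len(paths):
                    gaps.append((preset.label, si, "no input volume"))
                    continue
                try:
                    vol = read_volume(paths[si])
                except (OSError, DataError) as exc:
                    raise DataError(f"cannot read {paths[si]}: {exc}") from exc
            if roiset is None:
                pose = locate_phantom(vol)
                roiset = place_nema_rois(vol, pose)
            rc = recovery_coefficients(vol, roiset, config.h_true, config.b_true)
            for _, row in rc.table.iterrows():
                rc_rows.append((preset.label, si, row.sphere_mm, row.H_measured,
                                row.B_measured, row.RC))
            cnr = contrast_to_noise(vol, roiset)
            for _, row in cnr.table.iterrows():
                cnr_rows.append((preset.label, si, row.sphere_mm, row.S_hot,
                                 row.CNR))
            nps = volume_nps(vol, roiset, config.b_true,
                             normalization_power=config.nps_normalization_power)
            auc_rows.append((preset.label, si, nps.auc, nps.peak_frequency))
            for f, v in zip(nps.radial_freqs, nps.nps1d):
                curve_rows.append((preset.label, si, f, v))

    tables = {
        "rc": pd.DataFrame(rc_rows, columns=["condition", "scan", "sphere_mm",
                                             "H_measured", "B_measured", "RC"]),
        "cnr": pd.DataFrame(cnr_rows, columns=["condition", "scan", "sphere_mm",
                                               "S_hot", "CNR"]),
        "nps_auc": pd.DataFrame(auc_rows, columns=["condition", "scan", "auc_mm",
                                                   "peak_frequency_mm^-1"]),
        "nps_curves": pd.DataFrame(curve_rows, columns=["condition", "scan",
                                                        "frequency_mm^-1", "nps_mm^2"]),
        "gaps": pd.DataFrame(gaps, columns=["condition", "scan", "reason"]),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    _log_stage("nema", t0, conditions=len(config.conditions),
               scans=config.n_scans, ratio=f"{config.h_true}:{config.b_true}")
    return tables


def run_resolution_analysis(config: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-condition FWHM (radial/tangential per source) and MTF tables.

    The first repeat images the sources at their nominal positions; later
    repeats re-position them with a deterministic sub-pixel jitter, emulating
    physical re-placement of the capillary sources between repeat scans.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.ps_positions:
        raise DataError("no point-source positions configured")
    fwhm_rows, mtf_rows, lim_rows = [], [], []
    for ci, preset in enumerate(config.conditions):
        for rep in range(config.n_resolution_repeats):
            if rep == 0:
                positions = [tuple(p) for p in config.ps_positions]
            else:
                rng = np.random.default_rng(config.scan_seed(ci, rep) + 500009)
                jitter = rng.uniform(-0.4, 0.4, size=(len(config.ps_positions), 2))
                positions = [(py + jy * config.ps_pixel_spacing,
                              px + jx * config.ps_pixel_spacing)
                             for (py, px), (jy, jx) in zip(config.ps_positions, jitter)]
            vol = generate_point_sources(
                positions, amplitude=config.ps_amplitude,
                matrix_size=config.ps_matrix,
                pixel_spacing=config.ps_pixel_spacing)
            vol = apply_system_blur(vol, preset.psf_fwhm)
            for k, pos in enumerate(positions):
                for direction in ("radial", "tangential"):
                    pm = profile_fwhm(vol, pos, direction)
                    fwhm_rows.append((preset.label, rep, k, direction, pm.fwhm))
            center = positions[0]
            mtf = mtf_from_point_source(vol, center)
            lim_rows.append((preset.label, rep, mtf.limiting_resolution))
            for f, v in zip(mtf.freqs, mtf.mtf):
                mtf_rows.append((preset.label, rep, f, v))

    tables = {
        "fwhm": pd.DataFrame(fwhm_rows, columns=["condition", "repeat", "source",
                                                 "direction", "fwhm_mm"]),
        "mtf_curves": pd.DataFrame(mtf_rows, columns=["condition", "repeat",
                                                      "frequency_mm^-1", "mtf"]),
        "limiting_resolution": pd.DataFrame(
            lim_rows, columns=["condition", "repeat", "limiting_resolution_mm^-1"]),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    _log_stage("resolution", t0, conditions=len(config.conditions),
               repeats=config.n_resolution_repeats,
               sources=len(config.ps_positions))
    return tables


def _stats_findings(config: RunConfig, nema: dict, reso: dict) -> pd.DataFrame:
    rows = []
    labels = [c.label for c in config.conditions]

    # Friedman (+ Dunn) per sphere for RC and CNR, and on NPS AUC
    for metric, table, value in (("RC", nema["rc"], "RC"),
                                 ("CNR", nema["cnr"], "CNR")):
        for sphere, sub in table.groupby("sphere_mm"):
            panel = sub.pivot_table(index="scan", columns="condition",
                                    values=value).reindex(columns=labels)
            if panel.isna().any().any() or panel.shape[1] < 3:
                continue
            fr = friedman_test(panel)
            rows.append((metric, f"sphere {sphere:g} mm", "friedman",
                         fr.statistic, fr.p_value, fr.p_value < config.alpha))
            if fr.p_value < config.alpha:
                for _, d in dunn_posthoc(panel, config.dunn_adjust).iterrows():
                    rows.append((metric, f"sphere {sphere:g} mm",
                                 f"dunn {d.condition_a} vs {d.condition_b}",
                                 d.z, d.p_adj, d.p_adj < config.alpha))
    panel = nema["nps_auc"].pivot_table(index="scan", columns="condition",
                                        values="auc_mm").reindex(columns=labels)
    if not panel.isna().any().any() and panel.shape[1] >= 3:
        fr = friedman_test(panel)
        rows.append(("NPS AUC", "all spheres n/a", "friedman", fr.statistic,
                     fr.p_value, fr.p_value < config.alpha))
        if fr.p_value < config.alpha:
            for _, d in dunn_posthoc(panel, config.dunn_adjust).iterrows():
                rows.append(("NPS AUC", "", f"dunn {d.condition_a} vs {d.condition_b}",
                             d.z, d.p_adj, d.p_adj < config.alpha))

    # Tukey on MTF curves pooled over frequency points and repeats
    curves = {lab: sub["mtf"].to_numpy()
              for lab, sub in reso["mtf_curves"].groupby("condition")}
    if len(curves) >= 2:
        for _, d in curve_difference_test(curves).iterrows():
            rows.append(("MTF", "all frequencies",
                         f"tukey {d.condition_a} vs {d.condition_b}",
                         d.mean_difference, d.p_adj, d.p_adj < config.alpha))

    # paired t on FWHM for the configured condition pairs
    fw = reso["fwhm"]
    for (a, b) in config.fwhm_pairs:
        for direction in ("radial", "tangential"):
            va = fw[(fw.condition == a) & (fw.direction == direction)] \
                .sort_values(["repeat", "source"]).fwhm_mm.to_numpy()
            vb = fw[(fw.condition == b) & (fw.direction == direction)] \
                .sort_values(["repeat", "source"]).fwhm_mm.to_numpy()
            if va.size == 0 or vb.size == 0 or va.size != vb.size:
                continue
            t, p = paired_t(va, vb)
            rows.append(("FWHM", direction, f"paired t {a} vs {b}", t, p,
                         p < config.alpha))
    return pd.DataFrame(rows, columns=["metric", "detail", "comparison",
                                       "statistic", "p", "significant"])


def run_full_study(config: RunConfig, outdir: str | Path) -> dict:
    """Both analyses + statistics + a verifiable run manifest."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nema = run_nema_analysis(config, outdir)
    reso = run_resolution_analysis(config, outdir)
    findings = _stats_findings(config, nema, reso)
    findings.to_csv(outdir / "findings.csv", index=False)
    if config.figures:
        _make_figures(outdir, nema, reso)

    artifacts = sorted(p.name for p in outdir.glob("*.csv"))
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "alpha": config.alpha,
        "seeds": {
            f"{c.label}/scan{si}": config.scan_seed(ci, si)
            for ci, c in enumerate(config.conditions)
            for si in range(config.n_scans)
        },
        "artifacts": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in artifacts
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log_stage("full_study", t0, outdir=str(outdir),
               n_findings=len(findings))
    return {"nema": nema, "resolution": reso, "findings": findings,
            "manifest": manifest}


def verify_manifest(outdir: str | Path) -> list[str]:
    """Return a list of integrity problems ([] = manifest verifies)."""
    outdir = Path(outdir)
    try:
        with open(outdir / "manifest.json") as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        return ["manifest.json missing"]
    problems = []
    config = RunConfig.from_dict(manifest["config"])
    if config.digest() != manifest["config_sha256"]:
        problems.append("config hash mismatch (config or hash tampered)")
    for name, digest in manifest.get("artifacts", {}).items():
        f = outdir / name
        if not f.exists():
            problems.append(f"{name} missing")
        elif hashlib.sha256(f.read_bytes()).hexdigest() != digest:
            problems.append(f"{name} content differs from manifest")
    return problems


def _make_figures(outdir: Path, nema: dict, reso: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for lab, sub in nema["rc"].groupby("condition"):
        m = sub.groupby("sphere_mm").RC.mean()
        ax.plot(m.index, m.values, marker="o", label=lab)
    ax.set_xlabel("sphere diameter (mm)")
    ax.set_ylabel("recovery coefficient")
    ax.legend()
    fig.savefig(outdir / "rc.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for lab, sub in reso["mtf_curves"].groupby("condition"):
        m = sub.groupby("frequency_mm^-1").mtf.mean()
        ax.plot(m.index, m.values, label=lab)
    ax.set_xlabel("spatial frequency (mm$^{-1}$)")
    ax.set_ylabel("MTF")
    ax.set_xlim(0, 0.35)
    ax.legend()
    fig.savefig(outdir / "mtf.png", dpi=120)
    plt.close(fig)
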