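"""End-to-end pipeline: movie in, stiffness report out.

Stages: background subtraction -> registration -> segmentation -> tracking
(+ quality filter) -> PIV (+ divergence at nuclei) -> strain/stiffness
estimation.  Every stage writes its table to the output directory together
with a provenance record (config hash, package version, seed), and rerunning
with the same config and input reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .piv import VelocityField, divergence, divergence_at_nuclei, piv_field, replace_outliers
from .preprocess import RegistrationResult, estimate_background, register, subtract_background
from .segment import SegmentParams, segment_sequence
from .sequence import ImageSequence
from .stiffness import StiffnessModel, StiffnessResults
from .track import link, mean_spacing_um, monolayer_kinematics, quality_filter, velocities
from .windows import make_windows

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_against_tracking"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables, with defaults mirroring the analysis protocol
    (10 background iterations, degree-20 drift polynomial, aspect-ratio-3
    split, 10%/20% quality thresholds, PIV window slightly larger than the
    inter-nuclear distance)."""

    pixel_size_um: float
    dt_min: float
    # preprocessing
    subtract_bg: bool = True
    bg_iters: int = 10
    bg_frames: int = 10
    do_register: bool = True
    poly_degree: int = 20
    # segmentation
    nucleus_diameter_um: float = 16.0
    log_sigma_px: float | None = None
    open_radius_px: int = 1
    ar_split: float = 3.0
    # tracking
    max_disp_factor: float = 0.4     # x mean inter-nucleus spacing
    memory_frames: int = 1
    quality_window: int = 10
    quality_tol: float = 0.10
    quality_max_dropped: float = 0.20
    # PIV
    piv_window_um: float | None = None  # None: 1.2 x mean spacing
    piv_overlap: float = 0.5
    div_smooth_cells: float = 0.70
    # analysis windows and coupling fit
    n_windows: int = 5
    n_bins: int = 25
    fit_range_sigma: float = 1.0
    min_per_bin: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")

    def segment_params(self) -> SegmentParams:
        return SegmentParams(
            nucleus_diameter_um=self.nucleus_diameter_um,
            log_sigma_px=self.log_sigma_px,
            open_radius_px=self.open_radius_px,
            ar_split=self.ar_split,
        )

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    background: np.ndarray | None
    registration: RegistrationResult | None
    observations: pd.DataFrame
    trajectories: pd.DataFrame
    kinematics_pt: pd.DataFrame
    field: VelocityField
    data: pd.DataFrame                  # trajectories + div_h
    results: StiffnessResults


def run_pipeline(
    seq: ImageSequence,
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis on an image sequence.

    Raises a stage-named RuntimeError on failure; artifacts written before
    the failure are preserved in ``outdir``.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    background = None
    if cfg.subtract_bg:
        background = _stage("background", estimate_background, seq,
                            cfg.bg_iters, cfg.bg_frames, cfg.seed)
        seq = _stage("background", subtract_background, seq, background)
    registration = None
    if cfg.do_register:
        registration = _stage("register", register, seq, cfg.poly_degree)
        seq = registration.registered
        if out is not None:
            reg_tab = pd.DataFrame({
                "frame": np.arange(seq.n_frames),
                "dx_px": registration.dx_reg[:, 0], "dy_px": registration.dx_reg[:, 1],
                "x_reg_px": registration.x_reg[:, 0], "y_reg_px": registration.x_reg[:, 1],
                "x_cm_px": registration.x_cm[:, 0], "y_cm_px": registration.x_cm[:, 1],
                "x_noise_px": registration.x_noise[:, 0], "y_noise_px": registration.x_noise[:, 1],
            })
            reg_tab.to_csv(out / "registration.csv", index=False)

    observations, _labels = _stage("segment", segment_sequence, seq, cfg.segment_params())
    log.info("segment: %.1f nuclei/frame", observations.groupby("frame").size().mean())
    if out is not None:
        observations.to_csv(out / "observations.csv", index=False)

    spacing = mean_spacing_um(observations, seq.fov_area_um2)
    max_disp = cfg.max_disp_factor * spacing
    trajectories = _stage("track", link, observations, max_disp, cfg.memory_frames)
    trajectories = velocities(trajectories, seq.dt_min)
    trajectories, qstats = _stage("track", quality_filter, trajectories,
                                  cfg.quality_window, cfg.quality_tol,
                                  cfg.quality_max_dropped)
    kin_pt = monolayer_kinematics(trajectories)
    log.info("track: %d trajectories kept, %d dropped",
             qstats["dropped"].eq(False).sum(), qstats["dropped"].sum())
    if out is not None:
        trajectories.to_csv(out / "trajectories.csv", index=False)
        kin_pt.to_csv(out / "kinematics_tracking.csv", index=False)

    window_um = cfg.piv_window_um if cfg.piv_window_um is not None else 1.2 * spacing
    fld = _stage("piv", piv_field, seq, window_um, cfg.piv_overlap)
    fld = _stage("piv", replace_outliers, fld)
    fld = divergence(fld, cfg.div_smooth_cells)
    if out is not None:
        fld.kinematics().to_csv(out / "kinematics_piv.csv", index=False)

    data = _stage("piv", divergence_at_nuclei, fld, trajectories)
    duration_h = seq.duration_h
    windows = make_windows(duration_h, cfg.n_windows)
    model = StiffnessModel(data, seq.fov_area_um2, seq.dt_min,
                           observations=observations, windows=windows)
    results = _stage("strain", model.fit,
                     n_bins=cfg.n_bins, fit_range_sigma=cfg.fit_range_sigma,
                     min_per_bin=cfg.min_per_bin)
    if out is not None:
        results.save(out / "stiffness_report.json", out / "stiffness_report.csv")
        provenance = {
            "package": "nucleoflow",
            "version": __version__,
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "n_frames": seq.n_frames,
            "config": dataclasses.asdict(cfg),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=float)

    return PipelineResult(cfg, background, registration, observations,
                          trajectories, kin_pt, fld, data, results)


def validate_against_tracking(
    fld: VelocityField,
    trajectories: pd.DataFrame,
) -> dict:
    """Cross-validate PIV against particle tracking on the same movie.

    Compares per-frame v_cm and v_rms from the two routes (time-median of
    the relative difference) and the distributions of instantaneous speeds
    (two-sample Kolmogorov-Smirnov distance).
    """
    from scipy.stats import ks_2samp

    kin_pt = monolayer_kinematics(trajectories)
    kin_piv = fld.kinematics()
    merged = kin_pt.merge(kin_piv, on="frame", suffixes=("_pt", "_piv")).dropna()
    vrms_rel = np.abs(merged["v_rms_umh_piv"] - merged["v_rms_umh_pt"]) / merged["v_rms_umh_pt"]
    cm_pt = merged[["vcm_x_umh_pt", "vcm_y_umh_pt"]].to_numpy()
    cm_piv = merged[["vcm_x_umh_piv", "vcm_y_umh_piv"]].to_numpy()
    cm_diff = np.linalg.norm(cm_piv - cm_pt, axis=1)
    cm_scale = np.linalg.norm(cm_pt, axis=1)
    speeds_pt = np.hypot(trajectories["vx_umh"], trajectories["vy_umh"]).dropna()
    speeds_piv = fld.speed()[fld.valid]
    ks = ks_2samp(speeds_pt, speeds_piv.ravel())
    return {
        "v_rms_rel_diff": float(np.median(vrms_rel)),
        "v_cm_abs_diff_umh": float(np.median(cm_diff)),
        "v_cm_rel_diff": float(np.median(cm_diff / np.maximum(cm_scale, 1e-12))),
        "speed_ks_distance": float(ks.statistic),
        "per_frame": merged,
    }
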