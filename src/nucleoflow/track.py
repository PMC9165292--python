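"""Trajectory linking, monolayer kinematics and quality filtering.

Nucleus observations are linked frame-to-frame into trajectories with a
Crocker–Grier-style globally optimal assignment (squared-displacement cost,
solved with the Hungarian algorithm, with birth/death costs at the maximum
allowed displacement).  Gaps of up to ``memory`` missed frames are bridged.

From the trajectories the module derives per-step instantaneous velocities
``v_j = [x_j(t_{i+1}) - x_j(t_i)] / dt`` (µm/h), the monolayer
center-of-mass velocity (mean over nuclei per frame) and the RMS velocity in
the center-of-mass frame, plus the ensemble mean square displacement and its
ballistic-to-diffusive (persistent random walk) fit used to validate the
instantaneous-velocity assumption (``tau_p > dt``).

A photometric quality filter flags frames where the total nuclear intensity
``J`` deviates by more than 10% from its median over the previous 10 frames
(segmentation glitches: merges, splits, boundary leaks) and drops entire
trajectories that lose more than 20% of their frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment

__all__ = [
    "link",
    "velocities",
    "monolayer_kinematics",
    "quality_filter",
    "msd_persistence",
    "MSDResult",
    "mean_spacing_um",
]

log = logging.getLogger(__name__)

_BIG = 1e12


def mean_spacing_um(observations: pd.DataFrame, fov_area_um2: float) -> float:
    """Mean inter-nucleus spacing, sqrt(FOV area / mean count per frame)."""
    n = observations.groupby("frame").size().mean()
    return float(np.sqrt(fov_area_um2 / n))


def link(
    observations: pd.DataFrame,
    max_disp_um: float,
    memory: int = 1,
) -> pd.DataFrame:
    """Link per-frame observations into trajectories.

    Parameters
    ----------
    observations : DataFrame
        Must contain ``frame``, ``x_um``, ``y_um``; remaining columns are
        carried through.
    max_disp_um : float
        Maximum displacement per frame step; candidate links over gaps of
        ``g`` frames are allowed up to ``g * max_disp_um``.  A sensible
        default is ~0.4 x the mean inter-nucleus spacing.
    memory : int
        Number of consecutive missed frames a trajectory may survive.

    Returns the observation table with a ``track_id`` column, sorted by
    (track_id, frame).
    """
    if not len(observations):
        return observations.assign(track_id=pd.Series(dtype=int))
    obs = observations.sort_values("frame").reset_index(drop=True)
    track_id = np.full(len(obs), -1, int)

    # active tracks: (last_index, last_frame, x, y)
    active: list[list] = []
    next_id = 0
    frames = obs["frame"].to_numpy()
    xs = obs["x_um"].to_numpy()
    ys = obs["y_um"].to_numpy()

    for f in np.unique(frames):
        det_idx = np.nonzero(frames == f)[0]
        active = [a for a in active if f - a[1] <= memory + 1]
        n_a, n_d = len(active), len(det_idx)
        if n_a and n_d:
            ax = np.array([a[2] for a in active])
            ay = np.array([a[3] for a in active])
            gap = np.array([f - a[1] for a in active], float)
            d2 = (ax[:, None] - xs[det_idx][None, :]) ** 2 + \
                 (ay[:, None] - ys[det_idx][None, :]) ** 2
            gate2 = (gap[:, None] * max_disp_um) ** 2
            cost = np.where(d2 <= gate2, d2, _BIG)
            # square matrix with birth/death blocks priced at the gate
            C = np.full((n_a + n_d, n_a + n_d), 0.0)
            C[:n_a, :n_d] = cost
            C[:n_a, n_d:] = _BIG
            C[n_a:, :n_d] = _BIG
            np.fill_diagonal(C[:n_a, n_d:], gate2[:, 0] if gate2.ndim == 2 else gate2)
            np.fill_diagonal(C[n_a:, :n_d], (max_disp_um) ** 2)
            ri, ci = linear_sum_assignment(C)
            for r, c in zip(ri, ci):
                if r < n_a and c < n_d and cost[r, c] < _BIG:
                    j = det_idx[c]
                    track_id[j] = track_id[active[r][0]]
                    active[r] = [j, f, xs[j], ys[j]]
                elif r >= n_a and c < n_d:
                    j = det_idx[c]
                    track_id[j] = next_id
                    active.append([j, f, xs[j], ys[j]])
                    next_id += 1
        else:
            for j in det_idx:
                track_id[j] = next_id
                active.append([j, f, xs[j], ys[j]])
                next_id += 1
    obs = obs.assign(track_id=track_id)
    return obs.sort_values(["track_id", "frame"]).reset_index(drop=True)


def velocities(trajectories: pd.DataFrame, dt_min: float) -> pd.DataFrame:
    """Forward-difference velocity per consecutive frame pair, in µm/h.

    The velocity over the step ``t_i -> t_{i+1}`` is stored on the row of
    frame ``t_i``; rows without a consecutive successor get NaN.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    dt_h = dt_min / 60.0
    df = trajectories.sort_values(["track_id", "frame"]).copy()
    g = df.groupby("track_id")
    dx = g["x_um"].shift(-1) - df["x_um"]
    dy = g["y_um"].shift(-1) - df["y_um"]
    dframe = g["frame"].shift(-1) - df["frame"]
    step = dframe == 1
    df["vx_umh"] = np.where(step, dx / dt_h, np.nan)
    df["vy_umh"] = np.where(step, dy / dt_h, np.nan)
    return df


def monolayer_kinematics(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-frame center-of-mass velocity and RMS velocity fluctuation.

    ``v_cm`` is the mean nucleus velocity in the FOV; ``v_rms`` the root
    mean square of velocities in the center-of-mass frame.  Frames with
    fewer than 2 velocity-bearing nuclei are NaN.
    """
    df = trajectories
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df.dropna(subset=["vx_umh", "vy_umh"])
    rows = []
    for f, sub in df.groupby("frame"):
        if len(sub) < 2:
            rows.append({"frame": f, "vcm_x_umh": np.nan, "vcm_y_umh": np.nan,
                         "v_rms_umh": np.nan, "n": len(sub)})
            continue
        vx, vy = sub["vx_umh"].to_numpy(), sub["vy_umh"].to_numpy()
        cx, cy = vx.mean(), vy.mean()
        rows.append({
            "frame": f,
            "vcm_x_umh": cx,
            "vcm_y_umh": cy,
            "v_rms_umh": float(np.sqrt(np.mean((vx - cx) ** 2 + (vy - cy) ** 2))),
            "n": len(sub),
        })
    return pd.DataFrame(rows)


def quality_filter(
    trajectories: pd.DataFrame,
    window: int = 10,
    intensity_tol: float = 0.10,
    max_dropped_frac: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag unreliable segmentations by their total intensity.

    A frame of a trajectory is invalidated when its total intensity ``J``
    deviates from the median over the previous ``window`` validated frames
    by more than ``intensity_tol`` (fractional).  Frames without a full
    ``window``-frame history are exempt.  Trajectories losing more than
    ``max_dropped_frac`` of their frames are removed entirely.

    Returns ``(filtered, stats)``: the surviving trajectories with their
    ``valid`` column updated, and per-trajectory statistics
    (``track_id``, ``n_frames``, ``n_invalid``, ``dropped``).
    """
    df = trajectories.sort_values(["track_id", "frame"]).copy()
    valid = np.ones(len(df), bool)
    stats = []
    keep_track = {}
    pos = 0
    for tid, sub in df.groupby("track_id"):
        J = sub["J"].to_numpy(float)
        n = len(J)
        ok = np.ones(n, bool)
        history: list[float] = []
        for i in range(n):
            if len(history) >= window:
                med = float(np.median(history[-window:]))
                if med > 0 and abs(J[i] - med) > intensity_tol * med:
                    ok[i] = False
            if ok[i]:
                history.append(J[i])
        n_invalid = int((~ok).sum())
        dropped = n_invalid > max_dropped_frac * n
        stats.append({"track_id": tid, "n_frames": n, "n_invalid": n_invalid,
                      "dropped": dropped})
        keep_track[tid] = not dropped
        valid[pos:pos + n] = ok
        pos += n
    df["valid"] = df.get("valid", True) & valid
    stats = pd.DataFrame(stats)
    kept = df[df["track_id"].map(keep_track)].reset_index(drop=True)
    log.info("quality filter: %d/%d trajectories dropped",
             int(stats["dropped"].sum()), len(stats))
    return kept, stats


# ---------------------------------------------------------------------------
# Mean square displacement
# ---------------------------------------------------------------------------


@dataclass
class MSDResult:
    """Ensemble MSD in the center-of-mass frame and its PRW fit.

    The model is ``MSD(tau) = sigma_msd + 2 u^2 tau_p^2 (tau/tau_p - 1 +
    exp(-tau/tau_p))``: ballistic ``u^2 tau^2`` below the persistence time
    ``tau_p``, diffusive ``2 u^2 tau_p tau`` above, plus a constant offset
    from localization noise.
    """

    lag_h: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    speed_umh: float | None
    tau_p_h: float | None
    sigma_msd_um2: float | None
    fit_ok: bool

    def model(self, tau: np.ndarray) -> np.ndarray:
        return _prw(tau, self.speed_umh, self.tau_p_h, self.sigma_msd_um2)


def _prw(tau, u, tau_p, sigma):
    tau = np.asarray(tau, float)
    x = np.clip(tau / max(tau_p, 1e-12), 0, 700)
    return sigma + 2 * u**2 * tau_p**2 * (x - 1 + np.exp(-x))


def msd_persistence(
    trajectories: pd.DataFrame,
    dt_min: float,
    max_lag_frac: float = 1 / 3,
) -> MSDResult:
    """Ensemble-averaged MSD (center-of-mass frame) and its PRW fit.

    Positions are corrected for collective drift by subtracting, at each
    lag, the mean displacement of all nuclei over the same interval.  The
    fit returns the short-time speed ``u``, the persistence time ``tau_p``
    and the noise offset ``sigma_msd``; ``tau_p > dt`` justifies treating
    frame-to-frame displacements as instantaneous velocities.
    """
    dt_h = dt_min / 60.0
    piv_x = trajectories.pivot_table(index="frame", columns="track_id", values="x_um")
    piv_y = trajectories.pivot_table(index="frame", columns="track_id", values="y_um")
    X, Y = piv_x.to_numpy(), piv_y.to_numpy()
    T = X.shape[0]
    max_lag = max(2, int(T * max_lag_frac))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    npairs = np.empty(len(lags), int)
    for k, lag in enumerate(lags):
        dx = X[lag:] - X[:-lag]
        dy = Y[lag:] - Y[:-lag]
        # drift correction: per-time-origin mean displacement over nuclei
        dx = dx - np.nanmean(dx, axis=1, keepdims=True)
        dy = dy - np.nanmean(dy, axis=1, keepdims=True)
        sq = dx**2 + dy**2
        msd[k] = np.nanmean(sq)
        npairs[k] = np.isfinite(sq).sum()
    lag_h = lags * dt_h

    try:
        u0 = np.sqrt(max(msd[0], 1e-12)) / lag_h[0]
        p0 = [u0, max(lag_h[-1] / 5, dt_h), 0.0]
        popt, _ = curve_fit(_prw, lag_h, msd, p0=p0,
                            bounds=([0, 1e-6, 0], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
        return MSDResult(lag_h, msd, npairs, float(popt[0]), float(popt[1]),
                         float(popt[2]), True)
    except Exception as exc:  # noqa: BLE001 - fit failure is a reported state
        log.warning("MSD fit failed (%s); returning curve only", exc)
        return MSDResult(lag_h, msd, npairs, None, None, None, False)
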