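"""Particle image velocimetry and velocity-field divergence.

The monolayer velocity field is reconstructed per frame pair by FFT
cross-correlation of square interrogation windows with a size slightly
larger than the mean inter-nuclear distance (~14 µm), with three-point
subpixel peak refinement.  Outlier vectors are replaced by the median of
their valid neighbours.  The divergence field (1/h) is computed by central
differences (one-sided at the borders) and interpolated at nucleus centers
bicubically; its per-window standard deviation sigma_div tracks the
amplitude of local compression/dilation in the tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .sequence import ImageSequence
from .windows import TimeWindow

__all__ = [
    "VelocityField",
    "piv_field",
    "replace_outliers",
    "divergence",
    "divergence_at_nuclei",
    "divergence_spread",
]

log = logging.getLogger(__name__)


@dataclass
class VelocityField:
    """Gridded velocity field per frame pair.

    ``vx``, ``vy`` have shape (T-1, ny, nx) in µm/h; ``x_um``/``y_um`` are
    the window-center coordinates; ``valid`` flags reliable vectors.  The
    divergence grid (1/h) is attached by :func:`divergence`.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    dt_min: float
    window_um: float
    div: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return self.vx.shape[0]

    @property
    def dt_h(self) -> float:
        return self.dt_min / 60.0

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def kinematics(self) -> pd.DataFrame:
        """Per-frame-pair v_cm and v_rms over valid grid points."""
        rows = []
        for t in range(self.n_pairs):
            ok = self.valid[t]
            vx, vy = self.vx[t][ok], self.vy[t][ok]
            cx, cy = vx.mean(), vy.mean()
            rows.append({
                "frame": t,
                "vcm_x_umh": cx,
                "vcm_y_umh": cy,
                "v_rms_umh": float(np.sqrt(np.mean((vx - cx) ** 2 + (vy - cy) ** 2))),
                "n": int(ok.sum()),
            })
        return pd.DataFrame(rows)


def _subpixel_offset(c: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Three-point Gaussian (fallback parabolic) peak interpolation."""
    py, px = peak
    out = []
    for axis in (0, 1):
        if axis == 0:
            m, m0, p = c[py - 1, px], c[py, px], c[py + 1, px]
        else:
            m, m0, p = c[py, px - 1], c[py, px], c[py, px + 1]
        if m > 0 and m0 > 0 and p > 0:
            lm, l0, lp = np.log(m), np.log(m0), np.log(p)
            den = lm - 2 * l0 + lp
            d = 0.5 * (lm - lp) / den if abs(den) > 1e-12 else 0.0
        else:
            den = m - 2 * m0 + p
            d = 0.5 * (m - p) / den if abs(den) > 1e-12 else 0.0
        out.append(float(np.clip(d, -1, 1)))
    return out[0], out[1]


def piv_field(
    seq: ImageSequence,
    window_um: float = 14.0,
    overlap_frac: float = 0.5,
    min_window_px: int = 8,
    search_frac: float = 1 / 3,
) -> VelocityField:
    """Cross-correlation PIV on consecutive frame pairs.

    Windows are mean-subtracted and correlated circularly via FFT; the
    correlation peak is located within ``search_frac`` of the window size
    and refined to subpixel accuracy.  Windows with negligible texture are
    flagged invalid.
    """
    px = seq.pixel_size_um
    w = int(round(window_um / px))
    if w < min_window_px:
        raise ValueError(f"interrogation window {w} px < minimum {min_window_px} px")
    step = max(1, int(round(w * (1 - overlap_frac))))
    H, W = seq.frame_shape
    ys = np.arange(0, H - w + 1, step)
    xs = np.arange(0, W - w + 1, step)
    ny, nx = len(ys), len(xs)
    x_um = (xs + (w - 1) / 2) * px
    y_um = (ys + (w - 1) / 2) * px

    T = seq.n_frames
    vx = np.zeros((T - 1, ny, nx))
    vy = np.zeros((T - 1, ny, nx))
    valid = np.ones((T - 1, ny, nx), bool)
    max_disp = max(2, int(w * search_frac))

    # linear (zero-padded) cross-correlation, normalized by the number of
    # overlapping pixels per lag: the raw correlation is biased toward zero
    # displacement because large lags have fewer contributing pairs
    S = 2 * w - 1
    ctr = w - 1
    ov1d = w - np.abs(np.arange(S) - ctr).astype(float)
    overlap = np.outer(ov1d, ov1d)
    # mild Gaussian prior on the lag keeps the rim of the (variance-
    # amplifying) unbiased normalization from producing spurious far peaks;
    # near the true peak it changes 3-point ratios by <1e-2
    lag = np.arange(S) - ctr
    prior1d = np.exp(-(lag / (4.0 * max(max_disp, 1))) ** 2)
    weight = np.outer(prior1d, prior1d) / overlap

    for t in range(T - 1):
        f1 = np.asarray(seq.frames[t], float)
        f2 = np.asarray(seq.frames[t + 1], float)
        w1 = sliding_window_view(f1, (w, w))[::step, ::step][:ny, :nx]
        w2 = sliding_window_view(f2, (w, w))[::step, ::step][:ny, :nx]
        a = w1 - w1.mean(axis=(-2, -1), keepdims=True)
        b = w2 - w2.mean(axis=(-2, -1), keepdims=True)
        astd = a.std(axis=(-2, -1))
        bstd = b.std(axis=(-2, -1))
        # windows without real signal (nucleus-free: flat or pure shot
        # noise) produce random peaks; gate on contrast relative to the
        # frame as a whole
        std_floor = max(1e-9, 0.1 * f1.std())
        pa = np.zeros((ny, nx, S, S))
        pb = np.zeros((ny, nx, S, S))
        pa[..., :w, :w] = a
        pb[..., :w, :w] = b
        F1 = np.fft.rfft2(pa)
        F2 = np.fft.rfft2(pb)
        corr = np.fft.irfft2(F2 * np.conj(F1), s=(S, S))
        corr = np.roll(corr, (ctr, ctr), axis=(-2, -1)) * weight
        sub = corr[..., ctr - max_disp:ctr + max_disp + 1,
                   ctr - max_disp:ctr + max_disp + 1]
        flat = sub.reshape(ny, nx, -1)
        idx = flat.argmax(axis=-1)
        side = 2 * max_disp + 1
        pr = idx // side + ctr - max_disp
        pc = idx % side + ctr - max_disp
        for i in range(ny):
            for j in range(nx):
                if astd[i, j] < std_floor or bstd[i, j] < std_floor:
                    valid[t, i, j] = False
                    continue
                c = corr[i, j]
                peak = (pr[i, j], pc[i, j])
                if not (0 < peak[0] < S - 1 and 0 < peak[1] < S - 1):
                    valid[t, i, j] = False
                    continue
                dy_s, dx_s = _subpixel_offset(c, peak)
                dy = peak[0] - ctr + dy_s
                dx = peak[1] - ctr + dx_s
                vx[t, i, j] = dx * px / seq.dt_h
                vy[t, i, j] = dy * px / seq.dt_h
    return VelocityField(x_um, y_um, vx, vy, valid, seq.dt_min, window_um)


def replace_outliers(
    fieldv: VelocityField,
    vmax_umh: tuple[float, float] | None = None,
    robust_factor: float = 4.0,
    warn_frac: float = 0.30,
) -> VelocityField:
    """Replace outlier vectors with the median of their valid neighbours.

    A vector is an outlier when |vx| or |vy| exceeds the per-component
    threshold; by default the threshold is ``robust_factor`` x the
    per-frame robust standard deviation (1.4826 MAD) of each component
    around its median.  Invalid vectors are filled the same way.
    """
    vx, vy = fieldv.vx.copy(), fieldv.vy.copy()
    valid = fieldv.valid.copy()
    for t in range(fieldv.n_pairs):
        if vmax_umh is None:
            thr = []
            for comp in (vx[t], vy[t]):
                med = np.median(comp[valid[t]]) if valid[t].any() else 0.0
                mad = np.median(np.abs(comp[valid[t]] - med)) if valid[t].any() else 0.0
                thr.append(robust_factor * max(1.4826 * mad, 1e-12))
            ok = (np.abs(vx[t] - np.median(vx[t][valid[t]])) <= thr[0]) & \
                 (np.abs(vy[t] - np.median(vy[t][valid[t]])) <= thr[1])
        else:
            ok = (np.abs(vx[t]) <= vmax_umh[0]) & (np.abs(vy[t]) <= vmax_umh[1])
        bad = (~ok) | (~valid[t])
        frac = bad.mean()
        if frac > warn_frac:
            log.warning("frame pair %d: %.0f%% outlier vectors; field unreliable",
                        t, 100 * frac)
        if not bad.any():
            continue
        # iterative neighbour-median fill: isolated valid islands propagate
        good = ~bad
        for _ in range(max(vx[t].shape)):
            if good.all():
                break
            fill = ~good & (_neighbor_count(good) > 0)
            if not fill.any():
                break
            for comp in (vx[t], vy[t]):
                med = _neighbor_median(comp, good)
                comp[fill] = med[fill]
            good |= fill
        valid[t] = True
    out = VelocityField(fieldv.x_um, fieldv.y_um, vx, vy, valid,
                        fieldv.dt_min, fieldv.window_um, fieldv.div)
    return out


def _neighbor_count(good: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3))
    k[1, 1] = 0
    return ndimage.convolve(good.astype(float), k, mode="constant")


def _neighbor_median(comp: np.ndarray, good: np.ndarray) -> np.ndarray:
    """Median of the valid 8-neighbours of every grid point."""
    ny, nx = comp.shape
    stacks = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifted = np.full((ny, nx), np.nan)
            gs = np.full((ny, nx), False)
            ys0, ys1 = max(dy, 0), ny + min(dy, 0)
            xs0, xs1 = max(dx, 0), nx + min(dx, 0)
            shifted[ys0:ys1, xs0:xs1] = comp[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
            gs[ys0:ys1, xs0:xs1] = good[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
            shifted[~gs] = np.nan
            stacks.append(shifted)
    with np.errstate(all="ignore"):
        med = np.nanmedian(np.stack(stacks), axis=0)
    # no valid neighbour at all: fall back to global median of valid points
    if np.isnan(med).any():
        med = np.where(np.isnan(med), np.median(comp[good]) if good.any() else 0.0, med)
    return med


def divergence(fieldv: VelocityField, smooth_sigma_cells: float = 0.70) -> VelocityField:
    """Attach the divergence grid, in 1/h.

    Central differences on the interior, one-sided at grid borders
    (``numpy.gradient``); an optional Gaussian smoothing over
    ``smooth_sigma_cells`` grid cells suppresses grid-scale velocity noise,
    which otherwise dominates the derivative, while leaving fields that vary
    on the tissue scale essentially untouched (constants and affine fields
    are preserved exactly).
    """
    div = np.empty_like(fieldv.vx)
    dx = float(np.mean(np.diff(fieldv.x_um)))
    dy = float(np.mean(np.diff(fieldv.y_um)))
    for t in range(fieldv.n_pairs):
        d = np.gradient(fieldv.vx[t], dx, axis=1) + np.gradient(fieldv.vy[t], dy, axis=0)
        if smooth_sigma_cells > 0:
            d = ndimage.gaussian_filter(d, smooth_sigma_cells, mode="nearest")
        div[t] = d
    fieldv.div = div
    return fieldv


def divergence_at_nuclei(
    fieldv: VelocityField,
    trajectories: pd.DataFrame,
) -> pd.DataFrame:
    """Bicubic interpolation of the divergence at nucleus centers.

    For each observation at frame ``t`` (with ``t`` < last frame), the
    divergence of the field of frame pair ``(t, t+1)`` is evaluated at the
    nucleus center; nuclei outside the grid hull get NaN.  Returns the
    input table with a ``div_h`` column.
    """
    if fieldv.div is None:
        raise ValueError("divergence grid missing; call divergence() first")
    method = "cubic" if (len(fieldv.y_um) >= 4 and len(fieldv.x_um) >= 4) else "linear"
    out = trajectories.copy()
    out["div_h"] = np.nan
    for t in range(fieldv.n_pairs):
        sel = out["frame"] == t
        if not sel.any():
            continue
        interp = RegularGridInterpolator(
            (fieldv.y_um, fieldv.x_um), fieldv.div[t],
            method=method, bounds_error=False, fill_value=np.nan)
        pts = out.loc[sel, ["y_um", "x_um"]].to_numpy()
        out.loc[sel, "div_h"] = interp(pts)
    return out


def divergence_spread(
    div_at_nuclei: pd.DataFrame,
    windows: list[TimeWindow],
    dt_min: float,
    min_values: int = 30,
) -> pd.DataFrame:
    """Standard deviation of the per-nucleus divergence per time window."""
    dt_h = dt_min / 60.0
    rows = []
    for wdw in windows:
        t_h = div_at_nuclei["frame"].to_numpy() * dt_h
        vals = div_at_nuclei.loc[wdw.contains(t_h), "div_h"].dropna()
        rows.append({
            "window": wdw.label(),
            "t_mid_h": wdw.mid_h,
            "sigma_div_h": float(vals.std(ddof=1)) if len(vals) >= min_values else np.nan,
            "n": len(vals),
        })
    return pd.DataFrame(rows)
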