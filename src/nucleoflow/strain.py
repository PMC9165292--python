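"""Nuclear deformation statistics.

The projected nuclear area is non-stationary on experimental time scales
(slow growth/compression trends), so deformation amplitudes are quantified
through increments, in analogy with the mean squared displacement:

* the *nuclear strain* over a delay tau,
  ``da_j(tau|t) = [A_j(t+tau) - A_j(t)] / <A_j>``, normalized by the
  nucleus's own time-averaged area in the analysis window;
* the *mean square strain* ``MSS(tau) = <<da_j^2(tau|t)>_t>_j``, fitted with
  ``MSS(tau) = sigma_w + adot0 * tau_c * (1 - exp(-tau/tau_c))``: linear
  (diffusive-like) at short delays with characteristic strain rate
  ``adot0``, saturating beyond the correlation time ``tau_c``, with an
  offset ``sigma_w`` from delta-correlated area measurement noise;
* the *instantaneous strain rate*
  ``adot_j = (2/dt) (A(t+1) - A(t)) / (A(t+1) + A(t))`` (1/h);
* the normalized cross-correlation of ``adot_j`` with the local divergence,
  whose peak at zero delay signals an instantaneous (elastic) coupling;
* the binned regression of ``adot_j`` against the local divergence: its
  zero-intercept slope ``m`` near the origin gives the relative stiffness
  ``e_n = 1/m`` of the nucleus with respect to the whole cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .windows import TimeWindow

__all__ = [
    "MSSFit",
    "BinnedCoupling",
    "nuclear_strain",
    "mss",
    "fit_mss",
    "strain_rate",
    "strain_rate_table",
    "cross_correlation",
    "binned_coupling",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Mean square strain
# ---------------------------------------------------------------------------


def nuclear_strain(areas: np.ndarray, lag: int, mean_area: float) -> np.ndarray:
    """Strain increments ``da(tau|t)`` for one nucleus at a fixed lag.

    ``areas`` is the per-frame area series (NaN where missing); the
    normalization is the window-averaged area of the same nucleus.
    """
    a = np.asarray(areas, float)
    if lag < 1 or lag >= len(a):
        return np.empty(0)
    d = (a[lag:] - a[:-lag]) / mean_area
    return d[np.isfinite(d)]


def mss(
    trajectories: pd.DataFrame,
    dt_min: float,
    window: TimeWindow | None = None,
    max_lag_frac: float = 1 / 3,
    min_trajectories: int = 30,
) -> pd.DataFrame:
    """Mean square strain curve ``MSS(tau)``.

    Areas are organised per nucleus; for each lag (all integer multiples of
    the frame interval up to a third of the window) the squared strain
    increments are averaged over time origins and nuclei.  Returns a table
    with ``lag_h``, ``mss``, ``sem``, ``n``.
    """
    dt_h = dt_min / 60.0
    df = trajectories
    if "valid" in df.columns:
        df = df[df["valid"]]
    if window is not None:
        t_h = df["frame"].to_numpy() * dt_h
        df = df[window.contains(t_h)]
    piv = df.pivot_table(index="frame", columns="track_id", values="area_um2")
    n_traj = piv.shape[1]
    if n_traj < min_trajectories:
        log.warning("MSS: only %d trajectories in window (min %d)",
                    n_traj, min_trajectories)
    A = piv.to_numpy()
    mean_area = np.nanmean(A, axis=0)
    T = A.shape[0]
    max_lag = max(1, int(T * max_lag_frac))
    rows = []
    for lag in range(1, max_lag + 1):
        d = (A[lag:] - A[:-lag]) / mean_area[None, :]
        d2 = d[np.isfinite(d)] ** 2
        if len(d2) == 0:
            continue
        rows.append({
            "lag_h": lag * dt_h,
            "mss": float(d2.mean()),
            "sem": float(d2.std(ddof=1) / np.sqrt(len(d2))) if len(d2) > 1 else np.nan,
            "n": len(d2),
        })
    return pd.DataFrame(rows)


@dataclass
class MSSFit:
    """Parameters of the exponential MSS model (see module docstring)."""

    sigma_w: float          # noise offset, dimensionless strain^2
    adot0_h: float          # characteristic strain rate, 1/h
    tau_c_h: float          # correlation time, h
    cov: np.ndarray | None  # covariance of (sigma_w, adot0, tau_c)
    fit_ok: bool

    @property
    def adot0_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1])) if self.cov is not None else np.nan

    def model(self, tau_h: np.ndarray) -> np.ndarray:
        return _mss_model(np.asarray(tau_h, float),
                          self.sigma_w, self.adot0_h, self.tau_c_h)


def _mss_model(tau, sigma_w, adot0, tau_c):
    x = np.clip(tau / max(tau_c, 1e-9), 0, 700)
    return sigma_w + adot0 * max(tau_c, 1e-9) * (1 - np.exp(-x))


def fit_mss(curve: pd.DataFrame, min_points: int = 6) -> MSSFit:
    """Weighted least-squares fit of the exponential MSS model.

    Weights are 1/SEM^2; all parameters are constrained nonnegative.  The
    short-time slope of the fitted model equals ``adot0``.  On
    non-convergence, falls back to a linear short-time fit for ``adot0``.
    """
    tau = curve["lag_h"].to_numpy(float)
    y = curve["mss"].to_numpy(float)
    sem = curve["sem"].to_numpy(float)
    if len(tau) < min_points:
        raise ValueError(f"need at least {min_points} lag points, got {len(tau)}")
    sem = np.where(np.isfinite(sem) & (sem > 0), sem, np.nanmax(sem[sem > 0]) if (sem > 0).any() else 1.0)
    # initial guesses: offset from the smallest values, slope from the first lags
    slope0 = max((y[1] - y[0]) / (tau[1] - tau[0]), 1e-9) if len(y) > 1 else 1e-3
    p0 = [max(y[0] - slope0 * tau[0], 0.0), slope0, max(tau[-1] / 3, tau[0])]
    try:
        popt, pcov = curve_fit(
            _mss_model, tau, y, p0=p0, sigma=sem, absolute_sigma=True,
            bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20000)
        return MSSFit(float(popt[0]), float(popt[1]), float(popt[2]), pcov, True)
    except Exception as exc:  # noqa: BLE001
        log.warning("MSS fit failed (%s); falling back to linear short-time fit", exc)
        k = max(3, len(tau) // 4)
        a = np.polyfit(tau[:k], y[:k], 1)
        return MSSFit(max(float(a[1]), 0.0), max(float(a[0]), 0.0),
                      float("inf"), None, False)


# ---------------------------------------------------------------------------
# Instantaneous strain rate and its coupling to the divergence
# ---------------------------------------------------------------------------


def strain_rate(a1: np.ndarray, a2: np.ndarray, dt_h: float) -> np.ndarray:
    """Symmetric finite-difference area strain rate (1/h).

    ``adot = (2/dt) * (A2 - A1) / (A2 + A1)``; antisymmetric under swapping
    the two areas.
    """
    a1 = np.asarray(a1, float)
    a2 = np.asarray(a2, float)
    return (2.0 / dt_h) * (a2 - a1) / (a2 + a1)


def strain_rate_table(trajectories: pd.DataFrame, dt_min: float) -> pd.DataFrame:
    """Per-(nucleus, frame) strain rates from consecutive valid frames.

    The rate over ``(t_i, t_{i+1})`` is stored at frame ``t_i`` (matching
    the PIV field of the same frame pair).  Carries ``div_h`` through when
    present.
    """
    dt_h = dt_min / 60.0
    df = trajectories.sort_values(["track_id", "frame"]).copy()
    if "valid" in df.columns:
        df = df[df["valid"]]
    g = df.groupby("track_id")
    a_next = g["area_um2"].shift(-1)
    consecutive = (g["frame"].shift(-1) - df["frame"]) == 1
    adot = strain_rate(df["area_um2"].to_numpy(), a_next.to_numpy(), dt_h)
    out = df.assign(adot_h=np.where(consecutive, adot, np.nan))
    return out.dropna(subset=["adot_h"])


def cross_correlation(
    pairs: pd.DataFrame,
    dt_min: float,
    max_lag: int = 20,
    min_steps: int = 20,
) -> pd.DataFrame:
    """Time cross-correlation of strain rate and divergence, per nucleus,
    averaged over nuclei.

    Both series are mean-subtracted and normalized to unit variance per
    nucleus, so ``K(0) = 1`` for identical series.  Reported for negative
    and positive delays; zero-variance series are excluded.
    Expects columns ``track_id``, ``frame``, ``adot_h``, ``div_h``.
    """
    dt_h = dt_min / 60.0
    lags = np.arange(-max_lag, max_lag + 1)
    acc = np.zeros(len(lags))
    cnt = np.zeros(len(lags), int)
    n_used = 0
    for _, sub in pairs.groupby("track_id"):
        sub = sub.dropna(subset=["adot_h", "div_h"]).sort_values("frame")
        if len(sub) < min_steps:
            continue
        frames = sub["frame"].to_numpy()
        full = np.arange(frames.min(), frames.max() + 1)
        x = np.full(len(full), np.nan)
        y = np.full(len(full), np.nan)
        x[frames - frames.min()] = sub["adot_h"].to_numpy()
        y[frames - frames.min()] = sub["div_h"].to_numpy()
        xm, ym = np.nanmean(x), np.nanmean(y)
        xs, ys = np.nanstd(x), np.nanstd(y)
        if xs < 1e-12 or ys < 1e-12:
            continue
        x = (x - xm) / xs
        y = (y - ym) / ys
        n_used += 1
        for k, lag in enumerate(lags):
            if lag >= 0:
                prod = x[:len(x) - lag] * y[lag:]
            else:
                prod = x[-lag:] * y[:len(y) + lag]
            good = np.isfinite(prod)
            if good.any():
                acc[k] += np.nansum(prod[good])
                cnt[k] += good.sum()
    if n_used == 0:
        raise ValueError("no trajectory has enough common steps for the correlation")
    K = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame({"lag_h": lags * dt_h, "K": K, "n_pairs": cnt})


def correlation_peak(corr: pd.DataFrame) -> tuple[float, float]:
    """Location (h) and FWHM (h) of the cross-correlation peak."""
    lag = corr["lag_h"].to_numpy()
    K = corr["K"].to_numpy()
    i = int(np.nanargmax(K))
    peak_lag = float(lag[i])
    half = K[i] / 2
    above = K >= half
    width = (above.sum()) * float(np.mean(np.diff(lag)))
    return peak_lag, width


@dataclass
class BinnedCoupling:
    """Binned strain-rate/divergence scatter and its zero-intercept fit.

    ``m`` is the slope of the mean strain rate versus divergence in the
    near-origin fit range; ``e_n = 1/m`` is the relative nuclear stiffness.
    A free-intercept fit is also reported as a diagnostic.
    """

    bins: pd.DataFrame        # bin_center_h, adot_mean_h, sem, n
    m: float
    m_se: float
    e_n: float
    e_n_se: float
    fit_range_h: float
    sigma_div_h: float
    n_pairs: int
    intercept_free: tuple[float, float]  # (slope, intercept) diagnostic
    physical: bool

    def summary_row(self) -> dict:
        return {
            "m": self.m, "m_se": self.m_se, "e_n": self.e_n,
            "e_n_se": self.e_n_se, "sigma_div_h": self.sigma_div_h,
            "n_pairs": self.n_pairs, "physical": self.physical,
        }


def binned_coupling(
    pairs: pd.DataFrame,
    n_bins: int = 25,
    span_sigma: float = 3.0,
    fit_range_sigma: float = 1.0,
    min_per_bin: int = 50,
    min_pairs: int = 1000,
) -> BinnedCoupling:
    """Bin strain-rate/divergence pairs and fit the near-origin slope.

    Pairs are binned in equal-width divergence bins spanning
    ``+-span_sigma`` standard deviations; bins with fewer than
    ``min_per_bin`` pairs are dropped (the bin table is the scatter-plot
    summary).  The coupling ``m`` is the zero-intercept fit restricted to
    ``|div| <= fit_range_sigma * sigma_div``, computed on the raw pairs in
    range rather than on the bin means: bin means built from the same
    frames share their errors, so SEM-weighting them can badly skew the
    slope.  ``e_n = 1/m`` with its standard error by propagation (the
    slope SE is heteroscedasticity-robust).  ``m <= 0`` is flagged
    non-physical.
    """
    sub = pairs.dropna(subset=["adot_h", "div_h"])
    if len(sub) < min_pairs:
        log.warning("binned_coupling: only %d pairs (recommended >= %d)",
                    len(sub), min_pairs)
    x = sub["div_h"].to_numpy(float)
    y = sub["adot_h"].to_numpy(float)
    sigma = float(x.std(ddof=1))
    edges = np.linspace(-span_sigma * sigma, span_sigma * sigma, n_bins + 1)
    idx = np.digitize(x, edges) - 1
    rows = []
    for b in range(n_bins):
        m_b = idx == b
        n_b = int(m_b.sum())
        if n_b < min_per_bin:
            continue
        rows.append({
            "bin_center_h": 0.5 * (edges[b] + edges[b + 1]),
            "adot_mean_h": float(y[m_b].mean()),
            "sem": float(y[m_b].std(ddof=1) / np.sqrt(n_b)),
            "n": n_b,
        })
    bins = pd.DataFrame(rows)
    fit_range = fit_range_sigma * sigma
    in_range = np.abs(x) <= fit_range
    if in_range.sum() < 10:
        raise ValueError("fewer than 10 pairs inside the fit range")
    xf, yf = x[in_range], y[in_range]
    sxx = float(np.sum(xf * xf))
    m = float(np.sum(xf * yf) / sxx)
    resid = yf - m * xf
    m_se = float(np.sqrt(np.sum((xf * resid) ** 2)) / sxx)
    # free-intercept diagnostic
    slope_free, icept_free = (float(v) for v in np.polyfit(xf, yf, 1))
    physical = m > 0
    if physical:
        e_n = 1.0 / m
        e_n_se = m_se / m**2
    else:
        log.warning("non-positive coupling slope m=%.3g; e_n undefined", m)
        e_n, e_n_se = np.nan, np.nan
    return BinnedCoupling(bins, m, m_se, e_n, e_n_se, fit_range, sigma,
                          len(sub), (slope_free, icept_free), physical)
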