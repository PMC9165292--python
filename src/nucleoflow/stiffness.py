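"""Relative nuclear stiffness and the nucleus/cytoplasm modulus ratio.

The mechanical reading of the strain-rate/divergence coupling rests on two
ingredients:

* **continuity**: with a weakly inhomogeneous cell number density, the
  divergence of the monolayer velocity field equals the cell-area strain
  rate, ``div v = adot_c``; the fitted slope ``m`` of nuclear strain rate
  versus divergence is therefore the ratio of nuclear to cellular area
  strain rates, and its reciprocal ``e_n = 1/m`` a relative stiffness
  (large ``e_n``: the nucleus deforms little compared to the cell);
* a **series-elastic model** of the cell: an elastic nucleus (modulus
  ``E_n``) in series with an elastic cytoplasm (``E_cy``) under a common
  in-plane stress.  Writing the cell strain as an area-fraction-weighted
  sum of nuclear and cytoplasmic strains, ``a_c = beta a_n + (1-beta)
  a_cy`` with ``beta = <A_n>/<A_c>`` the nuclear area fraction, gives

      E_n / E_cy = (e_n - beta) / (1 - beta)

  which converts the kinematic observable ``e_n`` into a modulus ratio.

:class:`StiffnessModel` bundles the full estimation: per analysis window it
computes the divergence spread, the MSS fit, the binned coupling, ``beta``
and the modulus ratio with first-order error propagation, returning a
:class:`StiffnessResults` with a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .strain import BinnedCoupling, MSSFit, binned_coupling, fit_mss, mss, strain_rate_table
from .windows import TimeWindow, make_windows

__all__ = [
    "estimate_beta",
    "moduli_ratio",
    "window_report",
    "WindowEstimate",
    "StiffnessModel",
    "StiffnessResults",
]

log = logging.getLogger(__name__)


def estimate_beta(
    observations: pd.DataFrame,
    fov_area_um2: float,
    n_blocks: int = 5,
) -> tuple[float, float]:
    """Nuclear-to-cell projected area fraction ``beta`` with standard error.

    The mean cell area is the FOV area divided by the number of identified
    nuclei per frame, so per frame ``beta = <A_n> * N / FOV``.  When a
    ``border`` column is present, nuclei touching the FOV border are
    excluded from the mean area (their projected area is truncated) but
    still counted.  The SE is the standard deviation of the mean over
    ``n_blocks`` contiguous time sub-blocks (frames within a block are
    strongly correlated).
    """
    n_all = observations.groupby("frame").size()
    interior = observations
    if "border" in observations.columns:
        interior = observations[~observations["border"].astype(bool)]
    mean_area = interior.groupby("frame")["area_um2"].mean()
    per_frame = pd.DataFrame({"mean_area": mean_area, "n": n_all}).dropna()
    beta_t = (per_frame["mean_area"] * per_frame["n"] / fov_area_um2).to_numpy()
    beta = float(beta_t.mean())
    if len(beta_t) >= n_blocks:
        blocks = np.array_split(beta_t, n_blocks)
        bm = np.array([b.mean() for b in blocks])
        se = float(bm.std(ddof=1) / np.sqrt(len(bm)))
    else:
        se = float(beta_t.std(ddof=1) / np.sqrt(max(len(beta_t), 2)))
    if beta >= 1:
        log.warning("beta = %.3f >= 1: nuclei tile the full FOV", beta)
    return beta, se


def moduli_ratio(
    e_n: float,
    beta: float,
    e_n_se: float = 0.0,
    beta_se: float = 0.0,
) -> tuple[float, float, bool]:
    """Elastic modulus ratio ``E_n/E_cy = (e_n - beta)/(1 - beta)``.

    Standard error by first-order propagation assuming independent errors
    on ``e_n`` and ``beta``.  Returns ``(ratio, se, physical)``;
    ``e_n <= beta`` would imply a negative modulus and is flagged
    non-physical (with a warning) rather than raised.
    """
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    ratio = (e_n - beta) / (1 - beta)
    d_en = 1.0 / (1 - beta)
    d_beta = (e_n - 1.0) / (1 - beta) ** 2
    se = float(np.sqrt((d_en * e_n_se) ** 2 + (d_beta * beta_se) ** 2))
    physical = e_n > beta
    if not physical:
        log.warning("e_n=%.3g <= beta=%.3g: non-physical modulus ratio", e_n, beta)
    return float(ratio), se, physical


@dataclass
class WindowEstimate:
    """All stiffness-related estimates for one analysis window."""

    window: str
    t_mid_h: float
    m: float
    m_se: float
    e_n: float
    e_n_se: float
    beta: float
    beta_se: float
    e_ratio: float
    e_ratio_se: float
    adot0_h: float
    adot0_se_h: float
    tau_c_h: float
    sigma_w: float
    sigma_div_h: float
    n_pairs: int
    physical: bool


def window_report(results: list[WindowEstimate]) -> pd.DataFrame:
    """Tabulated time evolution of the per-window estimates."""
    if not results:
        raise ValueError("no window estimates to report")
    return pd.DataFrame([asdict(r) for r in results])


class StiffnessModel:
    """Relative-stiffness estimation from tracked areas and divergences.

    Parameters
    ----------
    data : DataFrame
        Per-(nucleus, frame) table with columns ``track_id``, ``frame``,
        ``area_um2``, ``div_h`` (local velocity divergence at the nucleus
        center) and optionally ``valid`` and ``border``.
    fov_area_um2 : float
        Field-of-view area, for the cell-area (and hence ``beta``) estimate.
    dt_min : float
        Frame interval in minutes.
    observations : DataFrame, optional
        Raw per-frame observation table used for ``beta`` (all identified
        nuclei, before trajectory filtering); defaults to ``data``.
    windows : list of TimeWindow, optional
        Analysis windows; default five half-overlapping windows covering
        the record.

    Examples
    --------
    >>> model = StiffnessModel(data, fov_area_um2=1.1e5, dt_min=5.0)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: pd.DataFrame,
        fov_area_um2: float,
        dt_min: float,
        observations: pd.DataFrame | None = None,
        windows: list[TimeWindow] | None = None,
    ) -> None:
        required = {"track_id", "frame", "area_um2", "div_h"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        self.data = data
        self.fov_area_um2 = float(fov_area_um2)
        self.dt_min = float(dt_min)
        self.observations = observations if observations is not None else data
        if windows is None:
            duration_h = data["frame"].max() * dt_min / 60.0
            windows = make_windows(duration_h)
        self.windows = windows

    @classmethod
    def from_tables(
        cls,
        trajectories: pd.DataFrame,
        div_at_nuclei: pd.DataFrame,
        fov_area_um2: float,
        dt_min: float,
        **kw,
    ) -> "StiffnessModel":
        """Build from a trajectory table and a per-(track, frame) divergence
        table (as produced by :func:`nucleoflow.piv.divergence_at_nuclei`)."""
        if "div_h" in trajectories.columns:
            data = trajectories
        else:
            data = trajectories.merge(
                div_at_nuclei[["track_id", "frame", "div_h"]],
                on=["track_id", "frame"], how="left")
        return cls(data, fov_area_um2, dt_min, **kw)

    # -- estimation ------------------------------------------------------
    def fit(
        self,
        n_bins: int = 25,
        span_sigma: float = 3.0,
        fit_range_sigma: float = 1.0,
        min_per_bin: int = 50,
        exclude_border: bool = True,
    ) -> "StiffnessResults":
        """Estimate m, e_n, beta and E_n/E_cy in every analysis window."""
        data = self.data
        if exclude_border and "border" in data.columns:
            data = data[~data["border"].astype(bool)]
        rates = strain_rate_table(data, self.dt_min)
        dt_h = self.dt_min / 60.0
        estimates: list[WindowEstimate] = []
        couplings: list[BinnedCoupling] = []
        mss_fits: list[MSSFit] = []
        for wdw in self.windows:
            in_w = wdw.contains(rates["frame"].to_numpy() * dt_h)
            pairs = rates[in_w]
            coup = binned_coupling(pairs, n_bins=n_bins, span_sigma=span_sigma,
                                   fit_range_sigma=fit_range_sigma,
                                   min_per_bin=min_per_bin)
            curve = mss(data, self.dt_min, window=wdw)
            msf = fit_mss(curve)
            obs_w = self.observations[
                wdw.contains(self.observations["frame"].to_numpy() * dt_h)]
            beta, beta_se = estimate_beta(obs_w, self.fov_area_um2)
            if coup.physical:
                ratio, ratio_se, physical = moduli_ratio(
                    coup.e_n, beta, coup.e_n_se, beta_se)
            else:
                ratio, ratio_se, physical = np.nan, np.nan, False
            estimates.append(WindowEstimate(
                window=wdw.label(), t_mid_h=wdw.mid_h,
                m=coup.m, m_se=coup.m_se,
                e_n=coup.e_n, e_n_se=coup.e_n_se,
                beta=beta, beta_se=beta_se,
                e_ratio=ratio, e_ratio_se=ratio_se,
                adot0_h=msf.adot0_h, adot0_se_h=msf.adot0_se,
                tau_c_h=msf.tau_c_h, sigma_w=msf.sigma_w,
                sigma_div_h=coup.sigma_div_h, n_pairs=coup.n_pairs,
                physical=physical,
            ))
            couplings.append(coup)
            mss_fits.append(msf)
        return StiffnessResults(self, estimates, couplings, mss_fits)


class StiffnessResults:
    """Fitted per-window stiffness estimates.

    Attributes
    ----------
    estimates : list of WindowEstimate
    couplings : list of BinnedCoupling (binned scatter + fit per window)
    mss_fits : list of MSSFit
    """

    def __init__(self, model: StiffnessModel, estimates: list[WindowEstimate],
                 couplings: list[BinnedCoupling], mss_fits: list[MSSFit]) -> None:
        self.model = model
        self.estimates = estimates
        self.couplings = couplings
        self.mss_fits = mss_fits

    def to_frame(self) -> pd.DataFrame:
        return window_report(self.estimates)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Human-readable per-window summary table."""
        df = self.to_frame()
        lines = [
            "Relative nuclear stiffness (series-elastic model)",
            "=" * 74,
            f"{'window':>10} {'m':>8} {'e_n':>14} {'beta':>14} {'E_n/E_cy':>14}",
            "-" * 74,
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['window']:>10} {r['m']:8.3f} "
                f"{r['e_n']:7.3f} ± {r['e_n_se']:5.3f} "
                f"{r['beta']:7.3f} ± {r['beta_se']:5.3f} "
                f"{r['e_ratio']:7.3f} ± {r['e_ratio_se']:5.3f}"
                + ("" if r["physical"] else "  [non-physical]"))
        lines.append("-" * 74)
        lines.append(f"{'adot0 (1/h)':>12} " + " ".join(
            f"{r['adot0_h']:8.4f}" for _, r in df.iterrows()))
        lines.append(f"{'sigma_div':>12} " + " ".join(
            f"{r['sigma_div_h']:8.4f}" for _, r in df.iterrows()))
        return "\n".join(lines)

    def save(self, json_path, csv_path=None) -> None:
        """Machine-readable report (JSON + optional CSV)."""
        df = self.to_frame()
        payload = {"windows": df.to_dict(orient="records")}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        if csv_path is not None:
            df.to_csv(csv_path, index=False)

    def plot_coupling(self, ax=None, window_index: int = 0):
        """Binned strain-rate vs divergence scatter with the fitted slope."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coup = self.couplings[window_index]
        ax.errorbar(coup.bins["bin_center_h"], coup.bins["adot_mean_h"],
                    yerr=coup.bins["sem"], fmt="o", ms=4, label="binned data")
        xx = np.linspace(-coup.fit_range_h, coup.fit_range_h, 50)
        ax.plot(xx, coup.m * xx, "-",
                label=f"m = {coup.m:.3f} (e_n = {coup.e_n:.2f})")
        ax.axvline(0, color="0.8", lw=0.5)
        ax.axhline(0, color="0.8", lw=0.5)
        ax.set_xlabel(r"divergence $\nabla\cdot v$ (1/h)")
        ax.set_ylabel(r"strain rate $\dot{a}_n$ (1/h)")
        ax.legend()
        return ax
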