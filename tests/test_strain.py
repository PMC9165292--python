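"""Mean square strain, strain rates, cross-correlation and binned coupling."""

import numpy as np
import pandas as pd
import pytest

from nucleoflow.strain import (
    binned_coupling,
    correlation_peak,
    cross_correlation,
    fit_mss,
    mss,
    nuclear_strain,
    strain_rate,
    strain_rate_table,
)
from nucleoflow.windows import TimeWindow


def _area_traj(areas, track_id=0):
    return pd.DataFrame({"track_id": track_id, "frame": np.arange(len(areas)),
                         "area_um2": areas})


class TestNuclearStrain:
    def test_constant_area_zero_strain(self):
        assert np.allclose(nuclear_strain(np.full(10, 50.0), 3, 50.0), 0.0)

    def test_hand_computed_value(self):
        # 100 -> 110 µm² with window-mean 100: strain 0.10
        d = nuclear_strain(np.array([100.0, 110.0]), 1, 100.0)
        assert d[0] == pytest.approx(0.10)

    def test_reverse_lag_antisymmetry(self):
        a = np.array([90.0, 100, 120, 95.0])
        fwd = nuclear_strain(a, 1, a.mean())
        rev = nuclear_strain(a[::-1], 1, a.mean())
        np.testing.assert_allclose(fwd, -rev[::-1])


class TestMSS:
    def test_constant_areas_zero_curve(self):
        trajs = pd.concat([_area_traj(np.full(30, 100.0), j) for j in range(5)])
        curve = mss(trajs, dt_min=5.0, min_trajectories=1)
        assert np.allclose(curve["mss"], 0.0)

    def test_iid_noise_plateau_2s2(self):
        rng = np.random.default_rng(0)
        mean_a, s = 200.0, 6.0
        trajs = pd.concat([
            _area_traj(mean_a + rng.normal(0, s, 400), j) for j in range(40)])
        curve = mss(trajs, dt_min=5.0, min_trajectories=1)
        expected = 2 * s**2 / mean_a**2
        np.testing.assert_allclose(curve["mss"], expected, rtol=0.1)

    def test_ou_areas_match_closed_form(self):
        rng = np.random.default_rng(1)
        theta, sig, mean_a = 2.0, 20.0, 300.0  # 1/h, µm²/sqrt(h), µm²
        dt_h = 1 / 12
        n_tracks, T = 60, 300
        # exact OU discretization: increments then match the continuous
        # closed form at every lag
        phi = np.exp(-theta * dt_h)
        s_eq = sig / np.sqrt(2 * theta)
        trajs = []
        for j in range(n_tracks):
            a = np.empty(T)
            a[0] = mean_a + rng.normal(0, s_eq)
            for t in range(1, T):
                a[t] = mean_a + phi * (a[t - 1] - mean_a) + \
                    s_eq * np.sqrt(1 - phi**2) * rng.normal()
            trajs.append(_area_traj(a, j))
        curve = mss(pd.concat(trajs), dt_min=5.0, min_trajectories=1)
        tau = curve["lag_h"].to_numpy()
        closed = 2 * (sig**2 / (2 * theta)) * (1 - np.exp(-theta * tau)) / mean_a**2
        np.testing.assert_allclose(curve["mss"], closed, rtol=0.15)


class TestFitMSS:
    def _curve(self, sigma_w, adot0, tau_c, noise=0.0, seed=0):
        tau = np.arange(1, 30) / 12
        y = sigma_w + adot0 * tau_c * (1 - np.exp(-tau / tau_c))
        rng = np.random.default_rng(seed)
        y = y * (1 + noise * rng.normal(size=len(tau)))
        return pd.DataFrame({"lag_h": tau, "mss": y, "sem": np.maximum(y * 0.02, 1e-8)})

    def test_model_parameters_recovered(self):
        fit = fit_mss(self._curve(0.001, 0.05, 0.5, noise=0.02))
        assert fit.fit_ok
        assert fit.adot0_h == pytest.approx(0.05, rel=0.1)
        assert fit.tau_c_h == pytest.approx(0.5, rel=0.1)
        assert fit.sigma_w == pytest.approx(0.001, rel=0.3)

    def test_pure_linear_curve_slope(self):
        tau = np.arange(1, 30) / 12
        y = 0.04 * tau
        curve = pd.DataFrame({"lag_h": tau, "mss": y, "sem": np.full(len(tau), 1e-5)})
        fit = fit_mss(curve)
        assert fit.adot0_h == pytest.approx(0.04, rel=0.05)
        assert fit.tau_c_h > tau[-1]  # effectively unbounded correlation time

    def test_flat_curve_goes_to_offset(self):
        tau = np.arange(1, 20) / 12
        curve = pd.DataFrame({"lag_h": tau, "mss": np.full(len(tau), 0.02),
                              "sem": np.full(len(tau), 1e-4)})
        fit = fit_mss(curve)
        assert fit.sigma_w + fit.adot0_h * fit.tau_c_h * 0 == pytest.approx(0.02, rel=0.2)
        assert fit.model(tau[0]) == pytest.approx(0.02, rel=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mss(pd.DataFrame({"lag_h": [0.1], "mss": [0.01], "sem": [1e-4]}))


class TestStrainRate:
    def test_constant_area_zero(self):
        assert strain_rate(100.0, 100.0, 0.1) == 0.0

    def test_hand_computed_value(self):
        # 100 -> 110 µm² over 0.1 h: (2/0.1)*(10/210)
        assert strain_rate(100.0, 110.0, 0.1) == pytest.approx(0.9524, abs=1e-4)

    def test_antisymmetric_under_swap(self):
        assert strain_rate(100.0, 120.0, 0.5) == -strain_rate(120.0, 100.0, 0.5)

    def test_table_pairs_consecutive_frames_only(self):
        df = pd.DataFrame({"track_id": 0, "frame": [0, 1, 3, 4],
                           "area_um2": [100.0, 110, 100, 90]})
        out = strain_rate_table(df, dt_min=6.0)
        assert list(out.frame) == [0, 3]


class TestCrossCorrelation:
    def _pairs(self, x, y, track_id=0):
        T = len(x)
        return pd.DataFrame({"track_id": track_id, "frame": np.arange(T),
                             "adot_h": x, "div_h": y})

    def test_identical_series_peak_unity_at_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        corr = cross_correlation(self._pairs(x, x), dt_min=5.0)
        k0 = corr.loc[corr.lag_h == 0, "K"].iloc[0]
        assert k0 == pytest.approx(1.0, abs=0.02)
        peak_lag, _ = correlation_peak(corr)
        assert peak_lag == 0.0

    def test_lagged_series_peak_at_lag(self):
        rng = np.random.default_rng(1)
        k = 4
        x = rng.normal(0, 1, 300)
        y = np.roll(x, k)  # y(t) = x(t - k): K(tau) peaks at tau = +k dt
        corr = cross_correlation(self._pairs(x[k:], y[k:]), dt_min=5.0)
        peak_lag, width = correlation_peak(corr)
        assert peak_lag == pytest.approx(k * 5 / 60, abs=1e-9)
        assert width > 0

    def test_independent_series_below_null_bound(self):
        rng = np.random.default_rng(2)
        N, M = 150, 30
        dfs = [self._pairs(rng.normal(0, 1, N), rng.normal(0, 1, N), j)
               for j in range(M)]
        corr = cross_correlation(pd.concat(dfs), dt_min=5.0)
        assert np.nanmax(np.abs(corr.K)) < 3 / np.sqrt(N * M)

    def test_zero_variance_series_excluded(self):
        with pytest.raises(ValueError):
            cross_correlation(self._pairs(np.ones(50), np.ones(50)), 5.0)


class TestBinnedCoupling:
    def _gen(self, slope, n=20000, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        div = rng.normal(0, 0.3, n)
        adot = slope * div + rng.normal(0, noise, n)
        return pd.DataFrame({"adot_h": adot, "div_h": div})

    def test_known_slope_recovered(self):
        c = binned_coupling(self._gen(0.5))
        assert c.m == pytest.approx(0.5, abs=0.05)
        assert c.e_n == pytest.approx(2.0, rel=0.1)
        assert c.physical

    def test_identity_coupling(self):
        c = binned_coupling(self._gen(1.0, noise=1e-6))
        assert c.m == pytest.approx(1.0, rel=0.01)
        assert c.e_n == pytest.approx(1.0, rel=0.01)

    def test_saturating_coupling_near_origin_slope(self):
        rng = np.random.default_rng(3)
        div = rng.normal(0, 0.3, 40000)
        sat = 0.08  # plateau of the nuclear strain rate
        adot = sat * np.tanh(0.5 * div / sat) + rng.normal(0, 0.02, len(div))
        pairs = pd.DataFrame({"adot_h": adot, "div_h": div})
        near = binned_coupling(pairs, fit_range_sigma=0.3)
        full = binned_coupling(pairs, fit_range_sigma=3.0)
        assert near.m == pytest.approx(0.5, rel=0.1)
        assert full.m < near.m  # full-range fit dilutes the small-signal slope

    def test_anticorrelated_flagged_nonphysical(self):
        c = binned_coupling(self._gen(-0.5))
        assert not c.physical
        assert np.isnan(c.e_n)

    def test_slope_invariant_to_bin_count(self):
        pairs = self._gen(0.5, n=30000)
        ms = [binned_coupling(pairs, n_bins=nb).m for nb in (15, 25, 45)]
        assert max(ms) - min(ms) < 0.05 * 0.5


def test_mss_windowing_uses_only_frames_in_window():
    areas = np.concatenate([np.full(20, 100.0), np.full(20, 300.0)])
    trajs = pd.concat([_area_traj(areas, j) for j in range(3)])
    w = TimeWindow(0.0, 19 * 5 / 60)
    curve = mss(trajs, dt_min=5.0, window=w, min_trajectories=1)
    assert np.allclose(curve["mss"], 0.0)
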