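"""Linking, kinematics, quality filter and MSD."""

import numpy as np
import pandas as pd
import pytest

from nucleoflow.track import (
    link,
    mean_spacing_um,
    monolayer_kinematics,
    msd_persistence,
    quality_filter,
    velocities,
)


def _obs(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


class TestLink:
    def test_single_nucleus_single_trajectory(self):
        rows = [(t, 10 + 0.5 * t, 20.0) for t in range(30)]
        trk = link(_obs(rows), max_disp_um=2.0)
        assert trk.track_id.nunique() == 1
        assert len(trk) == 30

    def test_no_identity_swaps_for_separated_walkers(self):
        rng = np.random.default_rng(1)
        n, T = 30, 100
        pos = np.stack(np.meshgrid(np.arange(5), np.arange(6)), -1).reshape(-1, 2) * 40.0 + 20
        rows = []
        for t in range(T):
            # displacement << 1/3 of the 40 µm spacing, bounded to the cage
            for j in range(n):
                rows.append({"frame": t, "x_um": pos[j, 0], "y_um": pos[j, 1],
                             "true_id": j})
            pos0 = np.stack(np.meshgrid(np.arange(5), np.arange(6)), -1).reshape(-1, 2) * 40.0 + 20
            pos = pos0 + np.clip(pos - pos0 + rng.normal(0, 1.5, (n, 2)), -6, 6)
        trk = link(pd.DataFrame(rows), max_disp_um=12.0)
        per_track = trk.groupby("track_id")["true_id"].nunique()
        assert per_track.max() == 1
        assert trk.track_id.nunique() == n

    def test_memory_bridges_single_frame_gap(self):
        rows = [(t, 50.0, 50.0) for t in range(10) if t != 4]
        trk = link(_obs(rows), max_disp_um=3.0, memory=1)
        assert trk.track_id.nunique() == 1

    def test_no_memory_splits_on_gap(self):
        rows = [(t, 50.0, 50.0) for t in range(10) if t != 4]
        trk = link(_obs(rows), max_disp_um=3.0, memory=0)
        assert trk.track_id.nunique() == 2


class TestVelocities:
    def test_hand_computed_step(self):
        df = pd.DataFrame({"track_id": [0, 0], "frame": [0, 1],
                           "x_um": [0.0, 1.0], "y_um": [0.0, 0.0]})
        v = velocities(df, dt_min=2.0)
        assert v.vx_umh.iloc[0] == pytest.approx(30.0)
        assert v.vy_umh.iloc[0] == pytest.approx(0.0)

    def test_static_nucleus_zero_velocity(self):
        df = pd.DataFrame({"track_id": 0, "frame": range(5),
                           "x_um": 3.0, "y_um": 4.0})
        v = velocities(df, 5.0)
        assert np.allclose(v.vx_umh.dropna(), 0)

    def test_velocity_requires_consecutive_frames(self):
        df = pd.DataFrame({"track_id": [0, 0], "frame": [0, 2],
                           "x_um": [0.0, 1.0], "y_um": [0.0, 0.0]})
        v = velocities(df, 5.0)
        assert v.vx_umh.isna().all()

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            velocities(pd.DataFrame({"track_id": [], "frame": [],
                                     "x_um": [], "y_um": []}), 0.0)


class TestKinematics:
    def test_uniform_translation(self):
        rows = []
        for tid, (x0, y0) in enumerate([(10, 10), (40, 10), (20, 40)]):
            for t in range(3):
                rows.append({"track_id": tid, "frame": t,
                             "x_um": x0 + 2.0 * t, "y_um": y0})
        kin = monolayer_kinematics(velocities(pd.DataFrame(rows), 60.0))
        assert kin.vcm_x_umh.iloc[0] == pytest.approx(2.0)
        assert kin.v_rms_umh.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_opposite_velocities(self):
        rows = []
        for tid, v in [(0, +3.0), (1, -3.0)]:
            for t in range(2):
                rows.append({"track_id": tid, "frame": t,
                             "x_um": 50 + v * t, "y_um": 10.0 + 30 * tid})
        kin = monolayer_kinematics(velocities(pd.DataFrame(rows), 60.0))
        assert kin.vcm_x_umh.iloc[0] == pytest.approx(0.0)
        assert kin.v_rms_umh.iloc[0] == pytest.approx(3.0)

    def test_isotropic_gaussian_vrms(self):
        rng = np.random.default_rng(0)
        sigma, n = 4.0, 4000
        rows = []
        for tid in range(n):
            vx, vy = rng.normal(0, sigma, 2)
            rows += [{"track_id": tid, "frame": 0, "x_um": 100.0 * tid, "y_um": 0.0},
                     {"track_id": tid, "frame": 1, "x_um": 100.0 * tid + vx, "y_um": vy}]
        kin = monolayer_kinematics(velocities(pd.DataFrame(rows), 60.0))
        assert kin.v_rms_umh.iloc[0] == pytest.approx(sigma * np.sqrt(2), rel=0.05)


class TestQualityFilter:
    def _traj(self, J):
        return pd.DataFrame({"track_id": 0, "frame": np.arange(len(J)),
                             "x_um": 0.0, "y_um": 0.0, "J": J})

    def test_constant_intensity_unflagged(self):
        kept, stats = quality_filter(self._traj(np.full(50, 100.0)))
        assert kept["valid"].all()
        assert not stats.dropped.any()

    def test_single_25pct_spike_flagged(self):
        J = np.full(60, 100.0)
        J[30] = 125.0
        kept, _ = quality_filter(self._traj(J))
        bad = kept.loc[~kept["valid"], "frame"].tolist()
        assert bad == [30]

    def test_exactly_10pct_not_flagged(self):
        J = np.full(60, 100.0)
        J[30] = 110.0  # deviation == 10%, rule requires "larger than"
        kept, _ = quality_filter(self._traj(J))
        assert kept["valid"].all()

    def test_trajectory_dropped_beyond_20pct(self):
        J = np.full(100, 100.0)
        J[60:85] = 130.0  # 25 deviant frames > 20%
        kept, stats = quality_filter(self._traj(J))
        assert stats.dropped.iloc[0]
        assert len(kept) == 0

    def test_first_frames_exempt(self):
        J = np.full(30, 100.0)
        J[3] = 200.0  # within the first 10 frames: no full history yet
        kept, _ = quality_filter(self._traj(J))
        assert kept["valid"].iloc[3]

    def test_order_independent_across_trajectories(self):
        rng = np.random.default_rng(0)
        dfs = []
        for tid in range(4):
            J = 100 + rng.normal(0, 6, 40)
            dfs.append(pd.DataFrame({"track_id": tid, "frame": np.arange(40),
                                     "x_um": 0.0, "y_um": 0.0, "J": J}))
        df = pd.concat(dfs, ignore_index=True)
        k1, s1 = quality_filter(df)
        k2, s2 = quality_filter(df.iloc[::-1].reset_index(drop=True))
        merged = k1.merge(k2, on=["track_id", "frame"], suffixes=("_a", "_b"))
        assert (merged.valid_a == merged.valid_b).all()


class TestMSD:
    def test_ballistic_motion_recovers_speed(self):
        rng = np.random.default_rng(3)
        rows = []
        u = 10.0
        for j in range(40):
            th = rng.uniform(0, 2 * np.pi)
            for t in range(60):
                rows.append({"track_id": j, "frame": t,
                             "x_um": u * np.cos(th) * t / 12,
                             "y_um": u * np.sin(th) * t / 12})
        res = msd_persistence(pd.DataFrame(rows), dt_min=5.0)
        assert res.fit_ok
        # center-of-mass correction removes 1/N of the variance
        assert res.speed_umh == pytest.approx(u * np.sqrt(1 - 1 / 40), rel=0.1)
        assert res.tau_p_h > 60 / 12 / 3  # lower-bounded by the window

    def test_brownian_motion_slope_4D(self):
        rng = np.random.default_rng(4)
        D = 2.0  # µm²/h
        dt_h = 1 / 12
        rows = []
        for j in range(60):
            xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt_h), (80, 2)), axis=0)
            for t in range(80):
                rows.append({"track_id": j, "frame": t,
                             "x_um": xy[t, 0], "y_um": xy[t, 1]})
        res = msd_persistence(pd.DataFrame(rows), dt_min=5.0)
        slope = np.polyfit(res.lag_h, res.msd_um2, 1)[0]
        assert slope == pytest.approx(4 * D, rel=0.2)

    def test_static_with_localization_noise_offset(self):
        rng = np.random.default_rng(5)
        sigma = 0.3
        rows = []
        for j in range(50):
            for t in range(40):
                rows.append({"track_id": j, "frame": t,
                             "x_um": 10.0 * j + rng.normal(0, sigma),
                             "y_um": rng.normal(0, sigma)})
        res = msd_persistence(pd.DataFrame(rows), dt_min=5.0)
        assert np.mean(res.msd_um2) == pytest.approx(4 * sigma**2, rel=0.25)


def test_mean_spacing():
    obs = pd.DataFrame({"frame": [0] * 25, "x_um": 0.0, "y_um": 0.0})
    assert mean_spacing_um(obs, 2500.0) == pytest.approx(10.0)
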