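"""Trajectory statistics against closed forms, brute-force and permutation oracles."""

import numpy as np
import pytest

from selfishherd import analysis
from selfishherd.environment import HerdFrame
from selfishherd.fixtures import (
    gas_trajectory,
    mill_trajectory,
    ring_frame,
    trajectory_from_frames,
    two_vortex_trajectory,
)
from selfishherd.geometry import compute_dod
from selfishherd.trajectory import Trajectory


def synthetic_traj(positions, headings=None, areas=None):
    """Trajectory stub with hand-set arrays (no geometric recomputation)."""
    positions = np.asarray(positions, float)
    T, n = positions.shape[:2]
    if headings is None:
        headings = np.zeros((T, n))
    if areas is None:
        areas = np.ones((T, n))
    z = np.zeros((T, n))
    return Trajectory(positions, np.asarray(headings, float), np.asarray(areas, float),
                      np.ones((T, n)), z, z.copy(), np.zeros((T - 1, n), dtype=int))


class TestMSD:
    def test_static_trajectory_has_zero_msd(self):
        pos = np.tile(np.array([[0.0, 0.0], [3.0, 1.0]]), (10, 1, 1))
        m = analysis.msd(synthetic_traj(pos), subtract_com=False)
        assert m.values == pytest.approx(np.zeros(9))

    def test_ballistic_agent_closed_form(self):
        v = 0.25
        t = np.arange(30)
        pos = np.stack([np.c_[v * t, np.zeros(30)]], axis=1)
        m = analysis.msd(synthetic_traj(pos), subtract_com=False)
        assert m.values == pytest.approx((v * m.lags) ** 2)

    def test_opposing_pair_with_com_subtraction(self):
        # two agents moving oppositely: COM static, each ballistic at speed v
        v = 0.1
        t = np.arange(25, dtype=float)
        pos = np.stack([np.c_[v * t, 0 * t], np.c_[-v * t, 0 * t]], axis=1)
        m = analysis.msd(synthetic_traj(pos), subtract_com=True)
        assert m.per_agent[:, 0] == pytest.approx((v * m.lags) ** 2)
        assert m.per_agent[:, 1] == pytest.approx((v * m.lags) ** 2)

    def test_com_subtraction_removes_rigid_drift(self, rng):
        pos = rng.uniform(0, 10, (1, 8, 2)) + rng.normal(0, 0.1, (40, 8, 2)).cumsum(0)
        drift = np.c_[0.3 * np.arange(40), -0.2 * np.arange(40)][:, None, :]
        a = analysis.msd(synthetic_traj(pos), subtract_com=True)
        b = analysis.msd(synthetic_traj(pos + drift), subtract_com=True)
        assert b.values == pytest.approx(a.values, rel=1e-9)


class TestRotationalOrder:
    def test_tangential_ring_is_a_perfect_mill(self):
        assert analysis.rotational_order(ring_frame(24)) == pytest.approx(1.0)

    def test_mixed_handedness_ring_cancels(self):
        hand = np.array([1] * 12 + [-1] * 12)
        assert analysis.rotational_order(ring_frame(24, handedness=hand)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_random_headings_scale_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(42)
        n = 10_000
        phi = 2 * np.pi * np.arange(n) / n
        frame = HerdFrame(0, 5.0 * np.c_[np.cos(phi), np.sin(phi)],
                          rng.uniform(0, 2 * np.pi, n))
        assert analysis.rotational_order(frame) < 0.03

    def test_printed_per_agent_absolute_variant_baseline(self):
        # the per-agent |.| form has baseline 2/pi for random headings
        rng = np.random.default_rng(0)
        n = 20_000
        phi = 2 * np.pi * np.arange(n) / n
        frame = HerdFrame(0, 5.0 * np.c_[np.cos(phi), np.sin(phi)],
                          rng.uniform(0, 2 * np.pi, n))
        val = analysis.rotational_order(frame, per_agent_abs=True)
        assert val == pytest.approx(2 / np.pi, abs=0.02)

    def test_mirror_image_has_equal_magnitude(self, random_frame):
        direct = analysis.rotational_order(random_frame)
        mirrored = HerdFrame(0, random_frame.positions * [1, -1],
                             (-random_frame.headings) % (2 * np.pi))
        assert analysis.rotational_order(mirrored) == pytest.approx(direct)

    def test_all_coincident_raises(self):
        with pytest.raises(ValueError):
            analysis.rotational_order(HerdFrame(0, np.zeros((3, 2)), np.zeros(3)))


class TestSpatialRotationMap:
    def test_single_mill_has_uniform_sign_near_rim(self):
        traj = mill_trajectory(n_rings=3, per_ring=8, n_frames=30)
        _, _, field = analysis.spatial_rotation_map(traj, grid_spacing=1.5)
        vals = field[np.isfinite(field)]
        assert vals.size > 4
        assert np.all(vals > 0)
        assert vals.max() > 0.9

    def test_two_vortex_map_shows_opposite_sign_lobes(self):
        # the map is centroid-relative, so off-centre vortices show with the
        # correct sign but reduced magnitude
        traj = two_vortex_trajectory()
        xc, _, field = analysis.spatial_rotation_map(traj, grid_spacing=1.5)
        left = field[:, xc < 0]
        right = field[:, xc > 0]
        assert np.nanmean(left) > 0.05
        assert np.nanmean(right) < -0.05
        # while the global signed order is near zero
        assert analysis.rotational_order(traj.frame(0)) < 0.05

    def test_static_gas_map_is_near_zero(self):
        traj = gas_trajectory(n=15, n_frames=60, rescatter=False, seed=2)
        _, _, field = analysis.spatial_rotation_map(traj, grid_spacing=4.0)
        vals = field[np.isfinite(field)]
        # headings are re-drawn each frame, so cell averages concentrate near 0
        assert np.abs(np.nanmean(vals)) < 0.15


class TestMedianAndCumulativeDOD:
    def test_median_is_robust_to_outliers(self):
        areas = np.tile(np.array([1.0, 2.0, 100.0]), (4, 1))
        med, _ = analysis.median_dod(synthetic_traj(np.zeros((4, 3, 2)) +
                                                    np.arange(3)[None, :, None],
                                                    areas=areas))
        assert med == pytest.approx([2.0] * 4)

    def test_constant_series_is_fixed_point(self):
        areas = np.full((10, 4), 7.5)
        cum = analysis.cumulative_dod(synthetic_traj(
            np.zeros((10, 4, 2)) + np.arange(4)[None, :, None], areas=areas))
        assert cum.per_agent == pytest.approx(np.full((10, 4), 7.5))

    def test_alternating_series_averages_pairwise(self):
        a, b = 2.0, 6.0
        areas = np.tile([[a], [b]], (5, 1)).reshape(10, 1)
        pos = np.zeros((10, 1, 2))
        traj = synthetic_traj(pos, areas=areas)
        cum = analysis.cumulative_dod(traj)
        even = cum.per_agent[1::2, 0]          # tau = 2, 4, ... frames
        assert even == pytest.approx(np.full(5, (a + b) / 2))

    def test_matches_prefix_sum_oracle(self, rng):
        areas = rng.uniform(1, 50, (30, 6))
        traj = synthetic_traj(np.zeros((30, 6, 2)) + np.arange(6)[None, :, None],
                              areas=areas)
        cum = analysis.cumulative_dod(traj)
        for tau in (1, 7, 30):
            assert cum.per_agent[tau - 1] == pytest.approx(areas[:tau].mean(axis=0))

    def test_distribution_rows_sum_to_one(self, rng):
        areas = rng.uniform(1, 50, (20, 8))
        traj = synthetic_traj(np.zeros((20, 8, 2)) + np.arange(8)[None, :, None],
                              areas=areas)
        _, _, probs = analysis.cumulative_dod_distribution(traj)
        assert probs.sum(axis=1) == pytest.approx(np.ones(20))


class TestDODACF:
    def test_lag_zero_is_one(self, rng):
        areas = rng.uniform(1, 10, (50, 5))
        acf = analysis.dod_acf(synthetic_traj(
            np.zeros((50, 5, 2)) + np.arange(5)[None, :, None], areas=areas))
        assert acf.values[0] == pytest.approx(1.0)

    def test_white_noise_decorrelates(self, rng):
        T = 2000
        areas = rng.normal(10, 1, (T, 10))
        acf = analysis.dod_acf(synthetic_traj(
            np.zeros((T, 10, 2)) + np.arange(10)[None, :, None], areas=areas),
            max_lags=30)
        assert np.all(np.abs(acf.values[1:]) < 3 / np.sqrt(T))

    def test_sinusoid_gives_cosine_with_window_bias(self):
        # the windowed estimator carries the standard (1 - tau/T) envelope
        P, T = 50, 1000
        t = np.arange(T)
        areas = np.tile(10 + np.sin(2 * np.pi * t / P)[:, None], (1, 3))
        acf = analysis.dod_acf(synthetic_traj(
            np.zeros((T, 3, 2)) + np.arange(3)[None, :, None], areas=areas),
            max_lags=60)
        small = acf.lags <= 2 * P
        expected = (1 - acf.lags[small] / T) * np.cos(2 * np.pi * acf.lags[small] / P)
        assert acf.values[small] == pytest.approx(expected, abs=0.02)

    def test_all_constant_areas_raise(self):
        with pytest.raises(ValueError):
            analysis.dod_acf(synthetic_traj(
                np.zeros((10, 3, 2)) + np.arange(3)[None, :, None]))


class TestNeighborPersistence:
    def test_frozen_configuration_keeps_all_neighbors(self):
        traj = gas_trajectory(n=15, n_frames=20, rescatter=False, seed=4)
        pnn = analysis.neighbor_persistence(traj)
        assert pnn.values == pytest.approx(np.ones(pnn.values.size))

    def test_lag_zero_is_one(self):
        traj = gas_trajectory(n=10, n_frames=5, rescatter=True, seed=1)
        pnn = analysis.neighbor_persistence(traj)
        assert pnn.values[0] == pytest.approx(1.0)

    def test_rescattered_gas_matches_permutation_oracle(self):
        # independent frames: p_NN(tau>0) equals the chance adjacency overlap,
        # estimated by pairing adjacency sets from unrelated frames
        traj = gas_trajectory(n=20, box_side=12.0, n_frames=40, rescatter=True, seed=7)
        pnn = analysis.neighbor_persistence(traj, max_lags=None)
        measured = pnn.values[1:].mean()

        sets = [compute_dod(traj.positions[t], traj.delta).neighbor_sets()
                for t in range(traj.n_frames)]
        rng = np.random.default_rng(11)
        chance = []
        for _ in range(400):
            t1, t2 = rng.choice(traj.n_frames, 2, replace=False)
            i = rng.integers(20)
            if sets[t1][i]:
                chance.append(len(sets[t1][i] & sets[t2][i]) / len(sets[t1][i]))
        chance = np.array(chance)
        se = chance.std(ddof=1) / np.sqrt(len(chance))
        assert abs(measured - chance.mean()) < max(3 * se, 0.02)


class TestRegimeSeparation:
    def test_rigid_rotation_versus_neighbor_shuffling(self):
        """A rigidly rotating, uniformly breathing ring keeps its Voronoi
        topology forever (p_NN = 1) and its periodic DOD signal recurs without
        decay; a re-scattered gas loses both — the statistics must separate the
        two regimes."""
        n, P, T = 20, 20, 60
        phi0 = 2 * np.pi * np.arange(n) / n
        frames = []
        for t in range(T):
            r = 4.0 * (1 + 0.15 * np.sin(2 * np.pi * t / P))
            phi = phi0 + 0.1 * t
            frames.append(HerdFrame(t, r * np.c_[np.cos(phi), np.sin(phi)],
                                    phi + np.pi / 2))
        rigid = trajectory_from_frames(frames)
        shuffled = gas_trajectory(n=18, box_side=12.0, n_frames=40, rescatter=True, seed=3)

        pnn_rigid = analysis.neighbor_persistence(rigid)
        pnn_shuffled = analysis.neighbor_persistence(shuffled)
        assert pnn_rigid.values.min() == pytest.approx(1.0)  # topology frozen
        assert pnn_shuffled.values[5:].mean() < 0.7

        acf_rigid = analysis.dod_acf(rigid, max_lags=40)
        acf_shuffled = analysis.dod_acf(shuffled, max_lags=20)
        # periodic signal recurs to the (1 - tau/T) estimator envelope at lag P
        at_period = acf_rigid.values[acf_rigid.lags == P][0]
        assert at_period == pytest.approx(1 - P / T, abs=0.05)
        assert analysis.correlation_time(acf_shuffled) < 10

        # a rigidly rotating circular mill has constant areas: ACF undefined
        with pytest.raises(ValueError):
            analysis.dod_acf(mill_trajectory(n_rings=1, per_ring=12, n_frames=10))

    def test_statistics_invariant_under_global_translation(self):
        traj = gas_trajectory(n=12, n_frames=25, rescatter=False, seed=9)
        shifted = Trajectory(
            traj.positions + np.array([100.0, -40.0]), traj.headings, traj.areas,
            traj.nn_dist, traj.r_shh, traj.r_prox, traj.actions, delta=traj.delta)
        a = analysis.msd(traj).values
        b = analysis.msd(shifted).values
        assert b == pytest.approx(a)
        assert analysis.rotational_order(shifted.frame(0)) == pytest.approx(
            analysis.rotational_order(traj.frame(0)))


def test_risk_spread_definition(rng):
    # IQR over agents of the cumulative mean DOD, divided by the ensemble mean
    areas = rng.uniform(5, 15, (30, 10))
    traj = synthetic_traj(np.zeros((30, 10, 2)) + np.arange(10)[None, :, None],
                          areas=areas)
    spread = analysis.risk_spread(traj)
    cum = np.cumsum(areas, axis=0) / np.arange(1, 31)[:, None]
    q1, q3 = np.percentile(cum, [25, 75], axis=1)
    assert spread.values == pytest.approx((q3 - q1) / cum.mean(axis=1))
    # averaging is contractive: the late spread is below the early spread
    assert spread.values[-1] < spread.values[0]


def test_msd_saturation_onset_on_synthetic_plateau():
    lags = np.arange(1, 201)
    values = 100 * (1 - np.exp(-lags / 20.0))
    onset = analysis.msd_saturation_onset(analysis.LagSeries(lags, values))
    # plateau estimate ~ 95.9 (mean over lags >= 20); its 95 % level is
    # crossed at t = -20 ln(1 - 0.911) ~ 48.4
    assert 45 <= onset <= 55
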