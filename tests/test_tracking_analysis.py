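"""Localization, linking, and dynamics statistics."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fsodt.forward_models import RIVolume
from fsodt.synthetic_data import (
    MotionModel,
    effective_buoyant_mass,
    hindered_parallel_diffusion,
    simulate_brownian_scene,
    simulate_swimmer_scene,
)
from fsodt.tracking_analysis import (
    Localization,
    LocalizeParams,
    Trajectory,
    boltzmann_height_fit,
    hindered_diffusion_fit,
    lag_time,
    link_trajectories,
    localize_particles,
    msd_diffusion,
    scene_to_localizations,
    stepsize_cdf,
    wobble_analysis,
)

N0 = 1.333


def gaussian_blob_volume(centers, amp=0.05, sigma=(0.8, 0.3, 0.3),
                         shape=(32, 64, 64), vz=0.4, vxy=0.2):
    data = np.zeros(shape)
    z = np.arange(shape[0])[:, None, None] * vz
    y = np.arange(shape[1])[None, :, None] * vxy
    x = np.arange(shape[2])[None, None, :] * vxy
    for (cz, cy, cx) in centers:
        data += amp * np.exp(
            -((z - cz) ** 2) / (2 * sigma[0] ** 2)
            - ((y - cy) ** 2) / (2 * sigma[1] ** 2)
            - ((x - cx) ** 2) / (2 * sigma[2] ** 2)
        )
    return RIVolume(N0 + data, vxy, vz, N0)


class TestLocalization:
    def test_constant_volume_yields_no_localizations(self):
        vol = RIVolume(np.full((16, 32, 32), N0, complex), 0.2, 0.4, N0)
        assert localize_particles(vol) == []

    def test_subvoxel_center_recovered(self):
        center = (6.13, 6.27, 5.91)
        vol = gaussian_blob_volume([center])
        locs = localize_particles(vol, LocalizeParams(expected_radius=0.5,
                                                      threshold=0.005))
        assert len(locs) == 1
        err = np.abs(locs[0].position - center)
        assert err[0] < 0.1 * 0.4 and err[1] < 0.1 * 0.2 and err[2] < 0.1 * 0.2

    def test_two_blobs_five_microns_apart(self):
        vol = gaussian_blob_volume([(6.0, 3.5, 3.5), (6.0, 8.5, 8.5)])
        locs = localize_particles(vol, LocalizeParams(expected_radius=0.5,
                                                      threshold=0.005))
        assert len(locs) == 2


class TestLinking:
    def _loc(self, pos, frame):
        return Localization(np.asarray(pos, float), 1.0, np.ones(3), 0.0, frame)

    def test_static_particle_single_track(self):
        frames = [[self._loc([5, 5, 5], t)] for t in range(100)]
        tracks = link_trajectories(frames, max_disp=1.0)
        assert len(tracks) == 1 and len(tracks[0]) == 100

    def test_well_separated_particles_match_optimal_assignment(self):
        rng = np.random.default_rng(0)
        base = np.array([[5.0, 2.0, 2.0], [5.0, 9.0, 9.0]])
        traj = [base + 0.1 * rng.standard_normal((2, 3))]
        for _ in range(30):
            traj.append(traj[-1] + 0.1 * rng.standard_normal((2, 3)))
        frames = [[self._loc(p, t) for p in pos] for t, pos in enumerate(traj)]
        tracks = link_trajectories(frames, max_disp=1.0)
        assert len(tracks) == 2
        # exhaustive optimal assignment oracle frame by frame
        for t in range(30):
            d = np.linalg.norm(traj[t][:, None] - traj[t + 1][None, :], axis=-1)
            rows, cols = linear_sum_assignment(d)
            for tr in tracks:
                i = {f: k for k, f in enumerate(tr.frames)}
                a = np.argmin(np.linalg.norm(traj[t] - tr.positions[i[t]], axis=1))
                b = np.argmin(np.linalg.norm(traj[t + 1] - tr.positions[i[t + 1]], axis=1))
                assert cols[rows == a][0] == b

    def test_linking_small_crowds_matches_assignment_oracle(self):
        # <= 5 particles, moderate motion: greedy linking equals the
        # exhaustive minimum-cost assignment between consecutive frames
        rng = np.random.default_rng(3)
        pos0 = rng.uniform(2, 10, (5, 3))
        pos1 = pos0 + 0.2 * rng.standard_normal((5, 3))
        frames = [
            [self._loc(p, 0) for p in pos0],
            [self._loc(p, 1) for p in pos1],
        ]
        tracks = link_trajectories(frames, max_disp=2.0)
        d = np.linalg.norm(pos0[:, None] - pos1[None, :], axis=-1)
        rows, cols = linear_sum_assignment(d)
        links = {}
        for tr in tracks:
            if len(tr) == 2:
                a = int(np.argmin(np.linalg.norm(pos0 - tr.positions[0], axis=1)))
                b = int(np.argmin(np.linalg.norm(pos1 - tr.positions[1], axis=1)))
                links[a] = b
        assert links == {int(a): int(b) for a, b in zip(rows, cols)}

    def test_gap_longer_than_memory_splits_track(self):
        frames = []
        for t in range(10):
            if 4 <= t < 6:
                frames.append([])
            else:
                frames.append([self._loc([5, 5, 5], t)])
        tracks = link_trajectories(frames, max_disp=1.0, memory=1)
        assert len(tracks) == 2
        joined = link_trajectories(frames, max_disp=1.0, memory=2)
        assert len(joined) == 1


class TestMSD:
    def test_ballistic_track_quadratic_msd(self):
        v = 2.0
        t = np.arange(50)
        pos = np.column_stack([np.zeros(50), np.zeros(50), v * t * 0.1])
        tr = Trajectory(0, t, pos)
        lags, msd, _ = msd_diffusion([tr], dt=0.1, fit_max_lag=0.5)
        assert np.allclose(msd, (v * lags) ** 2, rtol=1e-12)

    def test_brownian_tracks_recover_D_within_5_percent(self):
        model = MotionModel(diffusion_coefficient=0.8)
        scene = simulate_brownian_scene(
            model, 200, 1000, 0.01, seed=4, chamber_height=1e5,
            initial_positions=np.tile([5e4, 0, 0], (200, 1)),
        )
        tracks = [
            Trajectory(i, np.arange(1000), scene.positions[:, i])
            for i in range(200)
        ]
        _, _, D = msd_diffusion(tracks, dt=0.01, fit_max_lag=0.05)
        assert abs(D - 0.8) / 0.8 < 0.05

    def test_stride_subset_consistency(self):
        model = MotionModel(diffusion_coefficient=0.5)
        scene = simulate_brownian_scene(
            model, 5, 200, 0.01, seed=5, chamber_height=1e5,
            initial_positions=np.tile([5e4, 0, 0], (5, 1)),
        )
        tracks = [Trajectory(i, np.arange(200), scene.positions[:, i]) for i in range(5)]
        l1, m1, _ = msd_diffusion(tracks, dt=0.01, stride=1, max_lag_frames=32)
        l8, m8, _ = msd_diffusion(tracks, dt=0.01, stride=8, max_lag_frames=32)
        shared = np.isin(np.round(l1 / 0.01), np.round(l8 / 0.01))
        assert np.allclose(m1[shared], m8, rtol=1e-12)

    def test_error_when_no_track_long_enough(self):
        tr = Trajectory(0, [0], np.zeros((1, 3)))
        with pytest.raises(ValueError):
            msd_diffusion([tr], dt=0.1)


class TestStepSizeCDF:
    def test_deterministic_steps_give_unit_step_cdf(self):
        pos = np.column_stack([np.zeros(100), np.zeros(100), 0.3 * np.arange(100)])
        tr = Trajectory(0, np.arange(100), pos)
        xs, cdf, sigma, ks = stepsize_cdf([tr], lag=1, axis=2)
        assert np.allclose(xs, 0.3)
        assert sigma < 1e-12
        assert cdf[0] > 0 and np.isclose(cdf[-1], 1.0)

    def test_gaussian_steps_sigma_recovered(self):
        rng = np.random.default_rng(6)
        n = 10001
        steps = 0.5 * rng.standard_normal(n - 1)
        pos = np.column_stack([np.zeros(n), np.zeros(n), np.r_[0, np.cumsum(steps)]])
        tr = Trajectory(0, np.arange(n), pos)
        xs, cdf, sigma, ks = stepsize_cdf([tr], lag=1, axis=2)
        assert abs(sigma - 0.5) / 0.5 < 0.03
        assert ks < 0.02
        assert np.all(np.diff(cdf) >= 0) and 0 < cdf[0] <= 1

    def test_few_steps_warns(self, caplog):
        tr = Trajectory(0, np.arange(10), np.random.default_rng(0).random((10, 3)))
        with caplog.at_level("WARNING"):
            stepsize_cdf([tr], lag=1, axis=0)
        assert "only" in caplog.text


class TestHinderedDiffusion:
    def _exact_tracks(self, Do=0.06, R=0.5, dt=0.02):
        """Tracks whose lateral steps exactly realize D(h) at fixed heights."""
        tracks = []
        for i, h in enumerate(np.linspace(0.6, 5.4, 10)):
            D = hindered_parallel_diffusion(Do, R, h)
            step = np.sqrt(2 * D * dt)
            n = 40
            y = step * np.arange(n) * ((-1) ** np.arange(n)).cumsum() * 0  # placeholder
            # alternate +step/-step so each lag-1 displacement has |dy| = step
            dy = step * np.tile([1.0, -1.0], n // 2)
            dx = step * np.tile([1.0, -1.0], n // 2)
            pos = np.column_stack([np.full(n, h), np.r_[0, np.cumsum(dy)[:-1]],
                                   np.r_[0, np.cumsum(dx)[:-1]]])
            tracks.append(Trajectory(i, np.arange(n), pos))
        return tracks

    def test_exact_law_recovered_with_tiny_residuals(self):
        Do, R = 0.06, 0.5
        tracks = self._exact_tracks(Do, R)
        fit = hindered_diffusion_fit(tracks, dt=0.02, bin_edges_h=np.linspace(0.5, 5.5, 11))
        assert abs(fit.Do - Do) / Do < 1e-10
        assert abs(fit.R - R) / R < 1e-10
        model = hindered_parallel_diffusion(fit.Do, fit.R, fit.h_centers)
        assert np.abs(model - fit.D_of_h).max() < 1e-10

    def test_simulator_loop_closure(self):
        # the Brownian simulator's own trajectories reproduce the hindrance law
        model = MotionModel(diffusion_coefficient=0.06, bead_radius=0.5, hindered=True)
        scene = simulate_brownian_scene(model, 300, 600, 0.02, seed=7, chamber_height=6.0)
        tracks = link_trajectories(scene_to_localizations(scene), max_disp=3.0)
        fit = hindered_diffusion_fit(tracks, dt=0.02, bin_edges_h=np.linspace(0.5, 5.5, 11))
        assert abs(fit.Do - 0.06) / 0.06 < 0.05
        assert abs(fit.R - 0.5) / 0.5 < 0.10

    def test_single_bin_raises(self):
        tracks = self._exact_tracks()
        with pytest.raises(ValueError):
            hindered_diffusion_fit(tracks, dt=0.02, bin_edges_h=np.array([0, 10, 20, 30]))


class TestBoltzmann:
    def test_known_mass_recovered_within_10_percent(self):
        m = MotionModel(diffusion_coefficient=2.0, bead_radius=1.0, gravity=True,
                        bead_density=1.30, solvent_density=1.00)
        scene = simulate_brownian_scene(m, 100, 2000, 0.01, seed=2,
                                        chamber_height=12.0, substeps=5)
        tracks = [Trajectory(i, np.arange(2000), scene.positions[:, i])
                  for i in range(100)]
        m_fit, m_exp = boltzmann_height_fit(tracks, 1.0, 1.30, 1.00)
        assert abs(m_fit - m_exp) / abs(m_exp) < 0.10

    def test_neutral_buoyancy_flat_distribution(self, caplog):
        rng = np.random.default_rng(8)
        pos = np.column_stack([rng.uniform(1, 9, 2000), np.zeros(2000), np.zeros(2000)])
        tr = Trajectory(0, np.arange(2000), pos)
        with caplog.at_level("WARNING"):
            m_fit, m_exp = boltzmann_height_fit([tr], 0.5, 1.05, 1.05)
        assert m_exp == 0.0
        assert "neutral buoyancy" in caplog.text


class TestWobble:
    def test_aligned_swimmer_zero_angle(self):
        scene = simulate_swimmer_scene(20.0, 0.0, 100, 0.01, seed=0)
        res = wobble_analysis(scene, dt=0.01)
        assert len(res.wobble_angles) == 1
        assert abs(res.wobble_angles[0]) < 0.5

    def test_known_wobble_angle_recovered(self):
        scene = simulate_swimmer_scene(20.0, 20.0, 500, 0.01, seed=4,
                                       direction_diffusion=0.05)
        res = wobble_analysis(scene, dt=0.01)
        assert len(res.wobble_angles) == 1
        assert abs(res.wobble_angles[0] - 20.0) <= 2.0

    def test_short_track_excluded_by_length_filter(self):
        scene = simulate_swimmer_scene(20.0, 10.0, 49, 0.01, seed=5)
        res = wobble_analysis(scene, dt=0.01)
        assert res.wobble_angles == []

    def test_slow_track_excluded_by_distance_filter(self):
        scene = simulate_swimmer_scene(0.5, 10.0, 100, 0.01, seed=6)  # moves 0.5 um
        res = wobble_analysis(scene, dt=0.01)
        assert res.wobble_angles == []

    def test_segmentation_path_on_rasterized_rods(self):
        from fsodt.synthetic_data import rasterize_rods

        # 25 um/s for 0.3 s: a 7.5-um path that stays inside the volume
        scene = simulate_swimmer_scene(25.0, 15.0, 60, 0.005, seed=7,
                                       start=(6.4, 2.5, 6.4))
        vols = [
            rasterize_rods(scene.rods[t], (32, 64, 64), 0.2, 0.4, N0)
            for t in range(scene.n_frames)
        ]
        res = wobble_analysis(vols, dt=0.005, threshold=N0 + 0.02,
                              min_track_length=50, min_total_distance=4.0)
        assert len(res.wobble_angles) == 1
        # voxelization limits axis precision; a coarse band suffices
        assert abs(res.wobble_angles[0] - 15.0) < 5.0


def test_lag_time_arithmetic():
    assert lag_time(200, 1032.0) == pytest.approx(0.194, abs=5e-4)
    with pytest.raises(ValueError):
        lag_time(10, 0.0)
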