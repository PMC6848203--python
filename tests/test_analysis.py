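"""Analysis estimators against independent oracles and planted data."""

import numpy as np
import pytest

from lbmd.analysis import (DiffusionFit, diffusion_size_fit, gyration_dynamics,
                           gyration_tensor, membrane_thickness,
                           min_surface_distance, msd2d, msd2d_block,
                           oscillation_period, periodic_sd_diffusion,
                           radial_localisation, rdf, release_trace,
                           bonded_distributions)


class TestGyration:
    def test_unit_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        res = gyration_tensor(corners)
        np.testing.assert_allclose(res.eigenvalues, 0.25)
        assert res.rg2 == pytest.approx(0.75)

    def test_collinear_points_have_two_zero_eigenvalues(self):
        pts = np.outer(np.linspace(0, 9, 10), [1.0, 2.0, -1.0])
        res = gyration_tensor(pts)
        np.testing.assert_allclose(res.eigenvalues[1:], 0.0, atol=1e-12)

    def test_matches_covariance_oracle_on_random_clouds(self, rng):
        for _ in range(5):
            pts = rng.standard_normal((60, 3)) * [3.0, 2.0, 0.5]
            m = rng.uniform(1, 3, 60)
            res = gyration_tensor(pts, m)
            com = np.average(pts, axis=0, weights=m)
            d = pts - com
            S = np.einsum("n,ni,nj->ij", m, d, d) / m.sum()
            oracle = np.sort(np.linalg.eigvalsh(S))[::-1]
            np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-10)
            # eigenvectors diagonalise S with the right eigenvalues
            for k in range(3):
                v = res.eigenvectors[:, k]
                np.testing.assert_allclose(S @ v, res.eigenvalues[k] * v,
                                           atol=1e-8)

    def test_invariance_under_rigid_translation(self, rng):
        pts = rng.standard_normal((30, 3))
        a = gyration_tensor(pts).eigenvalues
        b = gyration_tensor(pts + [17.0, -4.0, 230.0]).eigenvalues
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_prolate_cloud_axis_projection(self, rng):
        # main axis ∥ x: the minor axes lie in the y-z plane, and the
        # z-projection of the third axis is bounded by 1
        pts = rng.standard_normal((500, 3)) * [5.0, 1.0, 0.6]
        out = gyration_dynamics(pts[None], tracked_bead=0)
        assert out["eigenvalues"][0, 0] > out["eigenvalues"][0, 2]
        assert 0.0 <= out["proj_axis3"][0] <= 1.0 + 1e-12
        assert 0.0 <= out["proj_tracked"][0] <= 1.0


class TestOscillationPeriod:
    def test_pure_sine_period_recovered(self):
        t = np.arange(0, 30, 0.01)
        tau = oscillation_period(np.sin(2 * np.pi * t / 1.0), dt=0.01)
        assert tau == pytest.approx(1.0, rel=0.02)

    def test_doubling_frequency_halves_period(self):
        t = np.arange(0, 30, 0.01)
        tau1 = oscillation_period(np.sin(2 * np.pi * t), dt=0.01)
        tau2 = oscillation_period(np.sin(4 * np.pi * t), dt=0.01)
        assert tau2 == pytest.approx(tau1 / 2, rel=0.02)

    def test_noisy_sine_within_5pct(self, rng):
        t = np.arange(0, 50, 0.01)
        x = np.sin(2 * np.pi * t / 2.5) + 0.1 * rng.standard_normal(len(t))
        assert oscillation_period(x, dt=0.01) == pytest.approx(2.5, rel=0.05)

    def test_featureless_noise_returns_none(self, rng):
        x = rng.standard_normal(2000)
        assert oscillation_period(x, dt=0.01, significance=50.0) is None


class TestThickness:
    @staticmethod
    def two_planes(dz=19.0, n=100, tilt=None, rng=None):
        rng = rng or np.random.default_rng(0)
        xy = rng.uniform(0, 300, (2 * n, 2))
        z = np.concatenate([np.full(n, 60 + dz), np.full(n, 60 - dz)])
        pts = np.column_stack([xy, z])
        if tilt is not None:
            pts = pts @ tilt.T
        return pts

    def test_synthetic_planes_give_38(self):
        pts = self.two_planes()
        assert membrane_thickness(pts, np.ones(len(pts), bool)) == pytest.approx(38.0)

    def test_rigid_translation_invariance(self):
        pts = self.two_planes()
        t1 = membrane_thickness(pts, np.ones(len(pts), bool))
        t2 = membrane_thickness(pts + [5.0, -3.0, 11.0], np.ones(len(pts), bool))
        assert t1 == pytest.approx(t2)

    def test_tilted_membrane_measured_along_fitted_normal(self):
        from scipy.spatial.transform import Rotation

        tilt = Rotation.from_euler("y", 20, degrees=True).as_matrix()
        pts = self.two_planes(tilt=tilt)
        t = membrane_thickness(pts, np.ones(len(pts), bool), fit_normal=True)
        assert t == pytest.approx(38.0, rel=0.01)

    def test_ambiguous_leaflets_raise(self):
        pts = self.two_planes(dz=1.0)
        with pytest.raises(ValueError):
            membrane_thickness(pts, np.ones(len(pts), bool))


class TestRdf:
    def test_ideal_gas_is_unity(self, rng):
        box = np.full(3, 40.0)
        frames = rng.uniform(0, 40, (20, 400, 3))
        r, g = rdf(frames, box, r_max=12.0, bins=24)
        np.testing.assert_allclose(g[r > 3.0], 1.0, atol=0.15)

    def test_simple_cubic_lattice_peaks(self):
        a = 5.0
        grid = np.array([[x, y, z] for x in range(8) for y in range(8)
                         for z in range(8)], dtype=float) * a
        box = np.full(3, 40.0)
        r, g = rdf(grid[None], box, r_max=12.0, bins=120)
        # peaks at a, a√2, a√3, 2a — and nothing below a
        assert g[(r > 1.0) & (r < a - 0.3)].max() == 0.0
        for d in (a, a * np.sqrt(2), a * np.sqrt(3), 2 * a):
            assert g[(r > d - 0.25) & (r < d + 0.25)].max() > 1.5

    def test_box_too_small_raises(self):
        with pytest.raises(ValueError):
            rdf(np.zeros((1, 10, 3)), np.full(3, 20.0), r_max=15.0)


class TestMsd:
    @staticmethod
    def brownian(rng, n=200, T=2000, dt=0.1, D=1.0):
        steps = rng.standard_normal((T, n, 2)) * np.sqrt(2 * D * dt)
        xy = np.cumsum(steps, axis=0)
        return np.concatenate([xy, np.zeros((T, n, 1))], axis=2)

    def test_recovers_generator_diffusion_within_2_se(self, rng):
        traj = self.brownian(rng, D=1.0)  # 200 ns at 0.1 ns/frame
        fit = msd2d_block(traj, dt=0.1, block_len=50.0, fit_window=(10.0, 20.0))
        assert abs(fit.D - 1.0) < 2 * fit.stderr + 0.02

    def test_immobile_particles_give_zero(self):
        traj = np.zeros((500, 20, 3))
        fit = msd2d_block(traj, dt=0.1, block_len=25.0, fit_window=(5.0, 10.0))
        assert fit.D == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_motion_flagged_nonlinear(self, caplog):
        t = np.arange(600) * 0.1
        traj = np.zeros((600, 10, 3))
        traj[:, :, 0] = (t**2)[:, None]  # accelerating: MSD ∝ t⁴
        with caplog.at_level("WARNING"):
            fit = msd2d_block(traj, dt=0.1, block_len=30.0, fit_window=(5.0, 15.0))
        assert not fit.linear

    def test_window_beyond_block_raises(self):
        with pytest.raises(ValueError):
            msd2d_block(np.zeros((100, 5, 3)), dt=0.1, block_len=5.0,
                        fit_window=(2.0, 10.0))

    def test_leaflet_drift_removal(self, rng):
        traj = self.brownian(rng, n=40, D=0.5)
        drift = np.cumsum(np.full((len(traj), 1, 3), [0.5, 0.0, 0.0]), axis=0)
        fit_drifting = msd2d_block(traj + drift, dt=0.1, block_len=50.0,
                                   fit_window=(10.0, 20.0),
                                   leaflet_masks=[np.arange(40)])
        assert abs(fit_drifting.D - 0.5) < 4 * fit_drifting.stderr + 0.05


class TestDiffusionSizeFit:
    def test_exact_loglinear_recovery(self):
        L = np.array([100.0, 150.0, 220.0, 330.0, 400.0])
        D = 2.0 + 0.7 * np.log(L)
        fit = diffusion_size_fit(L, D, model="loglinear")
        assert fit["a"] == pytest.approx(2.0, abs=1e-6)
        assert fit["c"] == pytest.approx(0.7, abs=1e-6)

    def test_constant_d_gives_zero_slope(self):
        L = np.array([100.0, 200.0, 300.0])
        fit = diffusion_size_fit(L, np.full(3, 5.0), model="loglinear")
        assert fit["c"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_replicates_recover_within_2_se(self, rng):
        L = np.array([100.0, 150.0, 220.0, 330.0, 400.0])
        truth_a, truth_c = 2.0, 0.7
        recovered = []
        for _ in range(100):
            D = truth_a + truth_c * np.log(L) + rng.normal(0, 0.05, len(L))
            recovered.append(diffusion_size_fit(L, D)["c"])
        mean_c = np.mean(recovered)
        se = np.std(recovered, ddof=1) / 10.0
        assert abs(mean_c - truth_c) < 2 * se + 1e-3

    def test_too_few_sizes_raise(self):
        with pytest.raises(ValueError):
            diffusion_size_fit([100.0, 200.0], [1.0, 2.0])

    def test_periodic_sd_model_grows_logarithmically(self):
        L = np.array([100.0, 200.0, 400.0, 800.0])
        D = np.array([periodic_sd_diffusion(l, eta_m=5.09e-8) for l in L])
        assert np.all(np.diff(D) > 0)
        # near-constant increments per doubling of L — the log signature
        inc = np.diff(D)
        assert inc[1] / inc[0] == pytest.approx(1.0, rel=0.35)
        assert inc[2] / inc[1] == pytest.approx(1.0, rel=0.35)

    def test_periodic_sd_fit_recovers_surface_viscosity(self):
        L = np.array([100.0, 150.0, 250.0, 400.0])
        truth = 5.09e-8
        D = np.array([periodic_sd_diffusion(l, eta_m=truth) for l in L])
        fit = diffusion_size_fit(L, D, model="periodic_sd", eta_m0=2e-8)
        assert fit["eta_m"] == pytest.approx(truth, rel=1e-3)

    def test_stronger_interleaflet_friction_slows_diffusion(self):
        fast = periodic_sd_diffusion(200.0, eta_m=5e-8, b=1e4)
        slow = periodic_sd_diffusion(200.0, eta_m=5e-8, b=1e7)
        assert slow < fast


class TestTransportObservables:
    def test_min_distance_of_probe_above_plane(self):
        plane = np.array([[x, y, 0.0] for x in range(0, 100, 10)
                          for y in range(0, 100, 10)], dtype=float)
        probe = np.array([[50.0, 50.0, 113.0]])
        traj = np.concatenate([probe, plane])[None]
        mask_p = np.zeros(len(traj[0]), bool)
        mask_p[0] = True
        series = min_surface_distance(traj, mask_p, ~mask_p,
                                      box=np.full(3, 400.0), bead_radius=2.35)
        assert series[0] == pytest.approx(113.0 - 2.35)

    def test_probe_inside_contact_from_start(self):
        plane = np.array([[x, y, 0.0] for x in range(0, 60, 6)
                          for y in range(0, 60, 6)], dtype=float)
        probe = np.array([[30.0, 30.0, 4.0]])
        frame = np.concatenate([probe, plane])
        traj = np.repeat(frame[None], 30, axis=0)
        mask_p = np.zeros(len(frame), bool)
        mask_p[0] = True
        _, t_ads = min_surface_distance(traj, mask_p, ~mask_p,
                                        box=np.full(3, 300.0), bead_radius=2.35,
                                        dt=0.1, sustain=1.0)
        assert t_ads == 0.0

    def test_translation_invariance(self):
        plane = np.array([[x, y, 0.0] for x in range(0, 60, 6)
                          for y in range(0, 60, 6)], dtype=float)
        frame = np.concatenate([[[30.0, 30.0, 40.0]], plane])
        mask_p = np.zeros(len(frame), bool)
        mask_p[0] = True
        box = np.full(3, 300.0)
        s1 = min_surface_distance(frame[None], mask_p, ~mask_p, box)
        s2 = min_surface_distance(frame[None] + 7.3, mask_p, ~mask_p, box)
        assert s1[0] == pytest.approx(s2[0])

    def test_uniform_cargo_density_is_flat(self, rng):
        # uniform points in a ball via rejection
        pts = rng.uniform(-1, 1, (40000, 3))
        pts = pts[np.linalg.norm(pts, axis=1) < 1.0] * 50.0
        out = radial_localisation(pts[None], {"s": np.arange(len(pts))},
                                  centre=np.zeros(3), r_max=50.0, bins=10)
        r, dens = out["s"]
        inner = dens[(r > 10) & (r < 45)]
        assert inner.std() / inner.mean() < 0.1

    def test_shell_cargo_gives_delta(self, rng):
        v = rng.standard_normal((5000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * 29.0
        out = radial_localisation(pts[None], {"s": np.arange(5000)},
                                  centre=np.zeros(3), r_max=40.0, bins=20)
        r, dens = out["s"]
        assert r[np.argmax(dens)] == pytest.approx(29.0, abs=2.0)
        assert np.sum(dens > 0) <= 2

    def test_mixture_matches_generator_within_l1(self, rng):
        # half uniform in ball radius 40, half shell at 25
        nu = 20000
        ball = rng.uniform(-1, 1, (3 * nu, 3))
        ball = ball[np.linalg.norm(ball, axis=1) < 1][:nu] * 40.0
        v = rng.standard_normal((nu, 3))
        shell = v / np.linalg.norm(v, axis=1, keepdims=True) * 25.5
        pts = np.concatenate([ball, shell])
        out = radial_localisation(pts[None], {"mix": np.arange(len(pts))},
                                  centre=np.zeros(3), r_max=45.0, bins=45)
        r, dens = out["mix"]
        dr = r[1] - r[0]
        # analytic mixture density (per-volume, normalised over 4πr²dr)
        expected = np.full_like(r, 0.5 / (4 / 3 * np.pi * 40.0**3))
        expected[r > 40.0] = 0.0
        k = np.argmin(np.abs(r - 25.5))
        shell_mass = np.zeros_like(r)
        shell_mass[k] = 0.5 / (4 * np.pi * r[k] ** 2 * dr)
        expected = expected + shell_mass
        l1 = np.sum(np.abs(dens - expected) * 4 * np.pi * r**2 * dr)
        assert l1 < 0.05

    def test_substrate_never_leaving_has_no_release(self):
        traj = np.zeros((100, 3, 3)) + 5.0
        traces, times = release_trace(traj, [np.array([0, 1, 2])],
                                      centre=np.array([5.0, 5.0, 5.0]),
                                      outer_radius=58.0, dt=0.1)
        assert times == [None]

    def test_scripted_escape_time_detected(self):
        T = 200
        traj = np.zeros((T, 1, 3))
        traj[:, 0, 0] = 5.0
        traj[120:, 0, 0] = 100.0  # leaves at frame 120
        traces, times = release_trace(traj, [np.array([0])],
                                      centre=np.zeros(3), outer_radius=58.0,
                                      dt=0.1, margin=10.0)
        assert times[0] == pytest.approx(12.0)

    def test_count_of_released_substrates(self):
        T = 150
        traj = np.zeros((T, 4, 3)) + 3.0
        traj[50:, 1, 2] = 90.0
        traj[100:, 3, 2] = 95.0
        _, times = release_trace(traj, [np.array([k]) for k in range(4)],
                                 centre=np.full(3, 3.0), outer_radius=58.0,
                                 dt=0.1)
        assert sum(t is not None for t in times) == 2


class TestBondedDistributions:
    def test_histograms_normalised_and_zero_t_is_delta(self):
        from lbmd.forcefield import BondTerm, Topology

        topo = Topology(["T", "T"], bonds=[BondTerm(0, 1, 4.7, 3.0)])
        topo.build_exclusions()
        frames = np.tile(np.array([[0.0, 0, 0], [4.7, 0, 0]]), (1200, 1, 1))
        out = bonded_distributions(frames, topo, box=np.full(3, 100.0))
        (centers, hist), = out.values()
        dr = centers[1] - centers[0]
        assert np.sum(hist) * dr == pytest.approx(1.0, rel=1e-6)
        assert np.sum(hist > 0) == 1  # delta at the minimum

    def test_langevin_dimer_matches_boltzmann_density(self):
        from lbmd.validate import bond_sampling_l1

        l1, info = bond_sampling_l1(seed=11, n_replicas=64, steps=20000)
        assert l1 < 0.03


class TestChargedDistances:
    def test_charged_pair_histogram_by_type(self):
        from lbmd.forcefield import Topology

        topo = Topology(["NC3", "PO4", "NC3", "PO4"])
        frames = np.tile(np.array([[0.0, 0, 0], [4.0, 0, 0],
                                   [0.0, 6.0, 0], [4.0, 6.0, 0]]),
                         (1000, 1, 1))
        out = bonded_distributions(frames, topo, box=np.full(3, 100.0),
                                   charges=np.array([1.0, -1.0, 1.0, -1.0]))
        assert "charged_NC3-PO4" in out
        assert "charged_NC3-NC3" in out
        r, dens = out["charged_NC3-PO4"]
        dr = r[1] - r[0]
        assert np.sum(dens) * dr == pytest.approx(1.0, rel=1e-6)
        # NC3-PO4 distances present at 4.0 and at √(16+36)
        assert dens[(r > 3.8) & (r < 4.2)].max() > 0
        assert dens[(r > np.sqrt(52) - 0.2) & (r < np.sqrt(52) + 0.2)].max() > 0
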