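"""Synthetic-data generator: motion statistics, dwell sampling, layouts, isotherms."""

import math

import numpy as np
import pytest
from scipy import stats

from smtrack import simkit
from smtrack.equilibria import fit_kd, fraction_bound_model
from smtrack.simkit import (
    SimulationConfig,
    fractional_gaussian_noise,
    lambda_fiducial_layout,
    make_damage_layout,
    render_kymograph,
    simulate_dwell_times,
    simulate_isotherm,
    simulate_trajectories,
)

from conftest import free_diffusion_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frame_interval": 0.0},
            {"frame_interval": -1.0},
            {"alpha": 0.0},
            {"alpha": 2.5},
            {"diffusion_coefficient": -1.0},
            {"diffusion_coefficient": float("nan")},
            {"photon_rate": 0.0},
            {"bind_lifetime": -2.0},
            {"kb_to_um": 0.0},
            {"dna_length": 1.0, "site_spacing": 2.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_observation_window(self):
        cfg = SimulationConfig(n_frames=3000, frame_interval=0.1)
        assert cfg.observation_window == pytest.approx(300.0)


class TestTrajectories:
    def test_degenerate_motion_is_constant(self):
        cfg = free_diffusion_config(
            diffusion_coefficient=0.0, localization_sigma=0.0, motile_fraction=0.0,
            dna_length=48.5,
        )
        trajs, truth = simulate_trajectories(cfg, 3, rng=np.random.default_rng(0))
        for t, p in zip(trajs, truth):
            assert np.all(t.positions_um == t.positions_um[0])
            assert not p.motile
            assert p.site_index is not None

    def test_brownian_increment_variance(self):
        # analytic increment variance of the Brownian model: 2 D dt = 0.004 um^2
        cfg = free_diffusion_config(
            n_frames=10_001, diffusion_coefficient=0.02, localization_sigma=0.0
        )
        trajs, _ = simulate_trajectories(cfg, 1, rng=np.random.default_rng(1))
        d = np.diff(trajs[0].positions_um)
        assert (d * d).mean() == pytest.approx(2 * 0.02 * 0.1, rel=0.05)

    def test_bleach_limited_track_duration(self):
        # exponential sampling oracle: mean duration ~ bleach lifetime
        cfg = free_diffusion_config(
            n_frames=3000, bleach_lifetime=40.4, localization_sigma=0.0,
            motile_fraction=0.0, dna_length=48.5,
        )
        trajs, _ = simulate_trajectories(cfg, 2000, rng=np.random.default_rng(2))
        durations = np.array([t.duration_s for t in trajs])
        se = 40.4 / math.sqrt(len(durations))
        assert abs(durations.mean() - 40.4) < 3 * se + cfg.frame_interval

    def test_truth_covers_every_rendered_frame(self):
        cfg = free_diffusion_config(n_frames=200, blink_on_lifetime=20.0)
        trajs, truth = simulate_trajectories(cfg, 5, rng=np.random.default_rng(3))
        for t, p in zip(trajs, truth):
            assert p.frames.size == len(t)
            assert p.true_positions_um.size == len(t)
            assert p.true_dwell_s == pytest.approx(
                len(p.states) * cfg.frame_interval - cfg.frame_interval
            )

    def test_determinism(self):
        cfg = free_diffusion_config(n_frames=100, rng_seed=7)
        a, _ = simulate_trajectories(cfg, 4)
        b, _ = simulate_trajectories(cfg, 4)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.frames, tb.frames)
            np.testing.assert_array_equal(ta.positions_um, tb.positions_um)

    def test_invalid_particle_count(self):
        with pytest.raises(ValueError):
            simulate_trajectories(free_diffusion_config(), 0)

    def test_scaled_increments_are_standard_normal(self):
        # Kolmogorov-Smirnov on increments / sqrt(2 D dt) at the 1% level
        cfg = free_diffusion_config(n_frames=5000, localization_sigma=0.0)
        trajs, _ = simulate_trajectories(cfg, 1, rng=np.random.default_rng(4))
        z = np.diff(trajs[0].positions_um) / math.sqrt(
            2 * cfg.diffusion_coefficient * cfg.frame_interval
        )
        assert stats.kstest(z, "norm").pvalue > 0.01


class TestFractionalGaussianNoise:
    @pytest.mark.parametrize("hurst", [0.35, 0.55, 0.65])
    def test_autocovariance_matches_theory(self, hurst):
        rng = np.random.default_rng(5)
        n, reps = 256, 400
        acf1 = []
        for _ in range(reps):
            x = fractional_gaussian_noise(n, hurst, rng)
            acf1.append(np.mean(x[:-1] * x[1:]))
        theory = simkit._fgn_autocovariance(2, hurst)[1]
        assert np.mean(acf1) == pytest.approx(theory, abs=0.02)

    def test_anomalous_msd_scaling(self):
        # Var over n steps must grow as (n dt)^alpha
        cfg = free_diffusion_config(
            n_frames=2000, alpha=1.3, diffusion_coefficient=0.02,
            localization_sigma=0.0,
        )
        trajs, _ = simulate_trajectories(cfg, 30, rng=np.random.default_rng(6))
        for lag in (1, 4, 16):
            sq = np.concatenate(
                [
                    (t.positions_um[lag:] - t.positions_um[:-lag]) ** 2
                    for t in trajs
                ]
            )
            expected = 2 * 0.02 * (lag * 0.1) ** 1.3
            assert sq.mean() == pytest.approx(expected, rel=0.12)

    def test_hurst_bounds(self):
        with pytest.raises(ValueError):
            fractional_gaussian_noise(10, 1.0, np.random.default_rng(0))


class TestKymograph:
    def test_empty_scene_is_constant_offset(self):
        cfg = free_diffusion_config(n_frames=20, dna_length=10.0)
        kymo = render_kymograph([], cfg, offset=7.0, shot_noise=False)
        assert np.all(kymo.data == 7.0)

    def test_stationary_emitter_peak_at_true_position(self):
        cfg = free_diffusion_config(
            diffusion_coefficient=0.0, localization_sigma=0.0, motile_fraction=0.0,
            n_frames=10, dna_length=10.0,
        )
        trajs, _ = simulate_trajectories(cfg, 1, rng=np.random.default_rng(7))
        kymo = render_kymograph(trajs, cfg, shot_noise=False)
        true_px = int(round(trajs[0].positions_um[0] / cfg.pixel_size))
        assert np.all(kymo.data.argmax(axis=0) == true_px)

    def test_poisson_photon_budget(self):
        # summed signal per frame (offset removed) ~ photon_rate * dt
        cfg = free_diffusion_config(
            diffusion_coefficient=0.0, localization_sigma=0.0, motile_fraction=0.0,
            n_frames=500, dna_length=10.0, photon_rate=2000.0,
        )
        trajs, _ = simulate_trajectories(cfg, 1, rng=np.random.default_rng(8))
        kymo = render_kymograph(
            trajs, cfg, offset=5.0, shot_noise=True, rng=np.random.default_rng(9)
        )
        per_frame = kymo.data.sum(axis=0) - 5.0 * kymo.n_pixels
        expected = cfg.photon_rate * cfg.frame_interval
        se = math.sqrt(expected / 500)
        assert abs(per_frame.mean() - expected) < 3 * se

    def test_counts_are_nonnegative_integers_before_offset(self):
        cfg = free_diffusion_config(n_frames=50, dna_length=10.0, motile_fraction=0.0)
        trajs, _ = simulate_trajectories(cfg, 2, rng=np.random.default_rng(10))
        kymo = render_kymograph(trajs, cfg, offset=0.0, rng=np.random.default_rng(11))
        assert np.all(kymo.data >= 0)
        assert np.all(kymo.data == np.round(kymo.data))

    def test_out_of_window_position_rejected(self):
        cfg = free_diffusion_config(n_frames=5, dna_length=10.0)
        from conftest import make_track

        bad = make_track([50.0] * 5)
        with pytest.raises(ValueError):
            render_kymograph([bad], cfg, n_pixels=20)


class TestDwellTimes:
    def test_exponential_mean(self):
        dw = simulate_dwell_times(5.0, float("inf"), 1e6, 10_000, rng=0)
        mean = np.mean([d.duration_s for d in dw])
        assert abs(mean - 5.0) < 3 * 5.0 / 100

    def test_competing_exponentials_harmonic_mean(self):
        # 1 / (1/2.8 + 1/40.4) = 2.6185 s
        dw = simulate_dwell_times(2.8, 40.4, 300.0, 10_000, rng=1)
        harmonic = 1 / (1 / 2.8 + 1 / 40.4)
        mean = np.mean([d.duration_s for d in dw])
        assert abs(mean - harmonic) < 3 * harmonic / 100

    def test_censoring_at_window(self):
        dw = simulate_dwell_times(200.0, float("inf"), 300.0, 2000, rng=2)
        for d in dw:
            assert d.duration_s <= 300.0
            assert d.censored == (d.duration_s == 300.0)
        assert any(d.censored for d in dw)

    @pytest.mark.parametrize("tau_off,tau_bleach", [(2.8, 40.4), (10.0, 10.0), (50.0, 5.0)])
    def test_competing_risk_grid(self, tau_off, tau_bleach):
        dw = simulate_dwell_times(tau_off, tau_bleach, 1e5, 5000, rng=3)
        harmonic = 1 / (1 / tau_off + 1 / tau_bleach)
        mean = np.mean([d.duration_s for d in dw])
        assert abs(mean - harmonic) < 3 * harmonic / math.sqrt(5000)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            simulate_dwell_times(5.0, 40.0, 0.0, 10)


class TestDamageLayouts:
    def test_array_every_2kb(self):
        # tightrope substrate: one lesion per 2 kb repeat
        layout = make_damage_layout("array", spacing=2.0, length=20.0)
        assert layout.sites.size == 10
        np.testing.assert_allclose(layout.sites, np.arange(2.0, 21.0, 2.0))

    def test_fiducial_ten_sites_reduce_to_eight(self):
        layout = lambda_fiducial_layout()
        assert layout.sites.size == 8

    def test_fiducial_merging_and_margin(self):
        layout = make_damage_layout(
            "fiducial",
            sites=[1.0, 5.0, 5.4, 8.0],
            length=10.0,
            resolution_limit=0.5,
            bead_margin=1.5,
        )
        # 1.0 inside the bead margin; 5.0/5.4 unresolved and merged to midpoint
        np.testing.assert_allclose(layout.sites, [5.2, 8.0])

    def test_empty_layout(self):
        layout = make_damage_layout(
            "fiducial", sites=[], length=10.0, resolution_limit=0.5, bead_margin=1.0
        )
        assert layout.sites.size == 0

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            make_damage_layout("array", spacing=0.0, length=10.0)


class TestIsotherm:
    def test_noiseless_identity(self):
        concs = np.linspace(0, 64, 9)
        pts = simulate_isotherm(6.0, 8.0, concs, noise_sd=0.0)
        for p in pts:
            assert p.percent_bound == pytest.approx(
                fraction_bound_model(8.0, p.protein_nM, 6.0)
            )

    def test_zero_protein_zero_bound(self):
        pts = simulate_isotherm(6.0, 8.0, [0.0], noise_sd=0.0)
        assert pts[0].percent_bound == 0.0

    def test_closed_loop_recovery(self):
        pts = simulate_isotherm(
            6.0, 8.0, np.geomspace(0.5, 128, 10), noise_sd=2.0, rng=4
        )
        fit = fit_kd(pts)
        assert fit.kd_nM == pytest.approx(6.0, rel=0.15)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_isotherm(6.0, 8.0, [1.0], noise_sd=-1.0)
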