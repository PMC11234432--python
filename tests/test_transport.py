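"""Brownian SPION transport: diffusion laws, capture statistics, well mode."""

import numpy as np
import pytest

from pvtarget.scenarios import straight_channel_mask
from pvtarget.transport import (RAPA_SPION, CaptureStats, TransportError,
                                TrajectoryResult, capture_stats,
                                diffusion_coefficient, free_diffusion_msd,
                                rapamycin_loading, sample_population, simulate)


class TestRapamycinLoading:
    def test_mass_balance(self):
        assert rapamycin_loading(2.5, 1.4) == pytest.approx(1.1)

    def test_default_is_study_loading(self):
        assert rapamycin_loading() == pytest.approx(1.1)

    def test_unbound_exceeding_stock_rejected(self):
        with pytest.raises(TransportError):
            rapamycin_loading(1.0, 1.4)


class TestDiffusionCoefficient:
    def test_stokes_einstein_reference(self):
        """D for the 78.9 nm drug-loaded SPION at 310 K in 1 mPa s."""
        assert diffusion_coefficient(78.9e-9, 310.0, 1e-3) == pytest.approx(
            5.75e-12, rel=0.01)

    def test_inverse_proportional_to_diameter(self):
        assert diffusion_coefficient(40e-9) == pytest.approx(
            2 * diffusion_coefficient(80e-9))

    def test_zero_temperature_limit(self):
        assert diffusion_coefficient(80e-9, 0.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(TransportError):
            diffusion_coefficient(-1e-9)


class TestPopulation:
    def test_drug_loaded_moments(self):
        pop = sample_population(n=10_000, seed=0)
        mean, sd = RAPA_SPION
        se = sd / np.sqrt(pop.n)
        assert abs(pop.diameters.mean() - mean) < 3 * se
        assert pop.diameters.std() == pytest.approx(sd, rel=0.1)
        assert np.all(pop.diameters > 0)

    def test_plain_spion_moments(self):
        pop = sample_population(n=10_000, mean_d=25.1e-9, sd_d=4.4e-9, seed=1)
        assert abs(pop.diameters.mean() - 25.1e-9) < 3 * 4.4e-9 / 100

    def test_degenerate_sd(self):
        pop = sample_population(n=100, sd_d=0.0, seed=0)
        assert np.all(pop.diameters == pop.diameters[0])

    def test_seed_determinism(self):
        a = sample_population(n=500, seed=42).diameters
        b = sample_population(n=500, seed=42).diameters
        assert np.array_equal(a, b)

    def test_extreme_skew_warns(self):
        with pytest.warns(UserWarning):
            sample_population(n=10, mean_d=10e-9, sd_d=20e-9, seed=0)


class TestFreeDiffusion:
    def test_msd_follows_4dt(self):
        pop = sample_population(n=10_000, sd_d=0.0, seed=1)
        t, msd = free_diffusion_msd(pop, duration=10.0, dt=0.05, seed=2)
        D = diffusion_coefficient(RAPA_SPION[0])
        assert msd[-1] == pytest.approx(4 * D * t[-1], rel=0.05)
        assert msd[len(msd) // 2] == pytest.approx(4 * D * t[len(t) // 2],
                                                   rel=0.05)


class TestSimulate:
    def test_seed_determinism(self):
        mask = straight_channel_mask()
        pop = sample_population(n=200, seed=5)
        a = simulate(pop, None, mask, None, duration=5.0, dt=0.05, seed=9)
        b = simulate(pop, None, mask, None, duration=5.0, dt=0.05, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.deposited, b.deposited)

    def test_particle_conservation(self):
        mask = straight_channel_mask()
        pop = sample_population(n=500, seed=3)
        traj = simulate(pop, None, mask, None, duration=20.0, dt=0.05, seed=4)
        assert (traj.deposited.sum() + traj.escaped.sum()
                + traj.suspended.sum()) == pop.n

    def test_deposited_particles_immobile(self):
        mask = straight_channel_mask()
        pop = sample_population(n=500, seed=3)
        traj = simulate(pop, None, mask, None, duration=20.0, dt=0.05, seed=4)
        if traj.deposited.any():
            assert np.all(np.isfinite(traj.deposit_pos[traj.deposited]))
            assert np.all(np.isfinite(traj.deposit_time[traj.deposited]))

    def test_outside_fluid_start_rejected(self):
        mask = straight_channel_mask()
        pop = sample_population(n=3, seed=0)
        bad = np.array([[8e-3, 5e-3]] * 3)  # outside the lumen
        with pytest.raises(TransportError):
            simulate(pop, None, mask, None, duration=1.0, dt=0.05, start=bad)


class TestCaptureStats:
    def _traj(self, n, dep_mask, pos):
        return TrajectoryResult(
            positions=pos, deposited=dep_mask,
            deposit_pos=np.where(dep_mask[:, None], pos, np.nan),
            deposit_time=np.where(dep_mask, 1.0, np.nan),
            escaped=np.zeros(n, dtype=bool))

    def test_all_in_target(self):
        mask = straight_channel_mask()
        c, r = mask.roi_centers["target"]
        n = 50
        pos = np.tile(c, (n, 1))
        stats = capture_stats(self._traj(n, np.ones(n, dtype=bool), pos), mask)
        assert stats.f_target == 1.0

    def test_no_deposits_flagged(self):
        mask = straight_channel_mask()
        n = 10
        pos = np.tile([8e-3, 0.0], (n, 1))
        stats = capture_stats(self._traj(n, np.zeros(n, dtype=bool), pos), mask)
        assert not stats.ratio_defined
        assert np.isnan(stats.ratio)

    def test_fraction_partition(self):
        mask = straight_channel_mask()
        pop = sample_population(n=1000, seed=7)
        traj = simulate(pop, None, mask, None, duration=30.0, dt=0.05, seed=8)
        stats = capture_stats(traj, mask)
        assert stats.fractions_sum(traj) == pytest.approx(1.0)

    def test_empty_ensemble_rejected(self):
        mask = straight_channel_mask()
        with pytest.raises(TransportError):
            capture_stats(self._traj(0, np.zeros(0, dtype=bool),
                                     np.zeros((0, 2))), mask)


class TestOrderingProperties:
    def test_capture_increases_with_remanence(self, run_config):
        """Two remanence levels, small ensemble: the magnet must help."""
        from pvtarget.scenarios import bifurcation_setup, channel_capture

        cfg = run_config.model_copy(deep=True)
        cfg.particles.n = 400
        cfg.particles.duration_s = 60.0
        mask, flow = bifurcation_setup(cfg)
        f0 = channel_capture(cfg, Br=0.0, seed=0, flow=flow, mask=mask).f_target
        f1 = channel_capture(cfg, Br=1.3, seed=0, flow=flow, mask=mask).f_target
        assert f1 > f0


class TestWellMode:
    def test_field_concentrates_deposits_centrally(self, run_config):
        from pvtarget.scenarios import dish_targeting

        res = dish_targeting(run_config, field_on=True, seed=5, n=2000,
                             duration=120.0)
        d = res.density
        r = res.r_centers
        assert d[r < 1e-3][0] > d[np.argmin(np.abs(r - 5e-3))]
        # non-increasing beyond the magnet edge (2 mm), up to noise
        beyond = d[r > 2.2e-3]
        assert np.all(np.diff(beyond) <= 0.15 * max(d.max(), 1))

    def test_field_off_is_uniform(self, run_config):
        from pvtarget.scenarios import dish_targeting

        res = dish_targeting(run_config, field_on=False, seed=6, n=20_000,
                             duration=60.0)
        # counts inside r < 5.5 mm vs uniform expectation, Poisson 3-sigma
        r_half = 5.5e-3
        area_frac = (r_half / 11e-3) ** 2
        counts_inner = res.density[res.r_centers < r_half] * np.pi * (
            np.diff(np.linspace(0, 11e-3, len(res.r_centers) + 1) ** 2)[
                res.r_centers < r_half])
        k_inner = counts_inner.sum()
        expect = res.n_deposited * area_frac
        assert abs(k_inner - expect) < 3 * np.sqrt(max(expect, 1.0)) + 3
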