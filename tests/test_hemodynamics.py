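"""Flow solver: waveform, Poiseuille/Womersley oracles, WSS, conservation."""

import numpy as np
import pytest

from pvtarget.geometry import BifurcationSpec, rasterize
from pvtarget.hemodynamics import (ML_PER_MIN, FlowConfig, FlowField,
                                   SolverError, WaveformError, make_waveform,
                                   sinusoid_waveform, solve_pulsatile,
                                   solve_steady, wss_with)


class TestWaveform:
    def test_default_reversal_peak(self):
        wf = make_waveform()
        t = np.linspace(0, wf.period, 2001)
        q = wf.rate(t)
        assert t[np.argmin(q)] == pytest.approx(0.24, abs=wf.period / 100)
        assert q.min() < 0

    def test_mean_normalization(self):
        wf = make_waveform()
        t = np.linspace(0, wf.period, 4001)
        assert np.trapezoid(wf.rate(t), t) / wf.period == pytest.approx(
            2.0, rel=0.01)

    def test_zero_amplitude_is_constant(self):
        wf = make_waveform(q_forward=2.0, q_reverse=2.0)
        t = np.linspace(0, 0.48, 100)
        assert np.allclose(wf.rate(t), 2.0)

    def test_periodic_samples(self):
        wf = make_waveform()
        t, q = wf.samples()
        assert q[0] == pytest.approx(q[-1], abs=1e-12)

    def test_bad_peak_time_rejected(self):
        with pytest.raises(WaveformError):
            make_waveform(t_peak_reverse=0.9)


@pytest.fixture(scope="module")
def steady_straight():
    """Steady 2 mL/min solve of a straight channel, 32 cells across."""
    spec = BifurcationSpec(branch_length=0.0, trunk_length=8e-3)
    mask = rasterize(spec, 2e-3 / 32)
    field = solve_steady(mask, FlowConfig(), Q_ml_min=2.0)
    return mask, field


class TestSteady:
    def test_parabolic_profile(self, steady_straight):
        mask, field = steady_straight
        uc, _ = field.center_velocity()
        h = mask.spacing
        y = mask.origin[1] + h * np.arange(mask.shape[1])
        H = 2e-3
        U = (2.0 * ML_PER_MIN) / H / H
        exact = 6 * U * ((y + 1e-3) / H) * (1 - (y + 1e-3) / H)
        prof = uc[mask.shape[0] // 2, :]
        assert np.max(np.abs(prof - exact)) / exact.max() < 0.05

    def test_wall_shear_stress_closed_form(self, steady_straight):
        mask, field = steady_straight
        w = wss_with(field, mask, 1e-3)
        mid = w[(w.x > 2e-3) & (w.x < 6e-3)]
        H = 2e-3
        U = (2.0 * ML_PER_MIN) / H / H
        tau_exact = 6 * 1e-3 * U / H
        assert np.abs(mid.tau).mean() == pytest.approx(tau_exact, rel=0.05)

    def test_flux_conservation(self, steady_straight):
        _, field = steady_straight
        assert field.flux_out() == pytest.approx(field.flux_in(), rel=0.01)

    def test_divergence_free(self, steady_straight):
        mask, field = steady_straight
        U = (2.0 * ML_PER_MIN) / 2e-3 / 2e-3
        scaled = np.abs(field.divergence()) * mask.spacing / U
        assert scaled.max() < 1e-6

    def test_no_slip_wss_sign_convention(self, steady_straight):
        """Forward flow drags both walls in +x: tau > 0 on y+ and y-."""
        mask, field = steady_straight
        w = wss_with(field, mask, 1e-3)
        assert (w[w.segment == "y+"].tau > 0).all()
        assert (w[w.segment == "y-"].tau > 0).all()

    def test_symmetric_bifurcation_splits_evenly(self, bifurcation_mask):
        field = solve_steady(bifurcation_mask, FlowConfig(), Q_ml_min=2.0)
        outs = field.outlet_fluxes()
        assert outs["outlet1"] == pytest.approx(outs["outlet2"], rel=0.01)
        total = sum(outs.values())
        assert total == pytest.approx(field.flux_in(), rel=0.01)

    def test_dynamic_pressure(self, steady_straight):
        mask, field = steady_straight
        q = field.dynamic_pressure(1000.0)
        fl = mask.fluid_mask()
        assert np.nanmin(q[fl]) >= 0
        # maximum on the channel axis where the parabola peaks
        imax = np.unravel_index(np.nanargmax(np.where(fl, q, np.nan)),
                                q.shape)
        y = mask.origin[1] + mask.spacing * imax[1]
        assert abs(y) < 2 * mask.spacing

    def test_reynolds_limit_enforced(self, steady_straight):
        mask, _ = steady_straight
        with pytest.raises(SolverError, match="Reynolds"):
            solve_steady(mask, FlowConfig(), Q_ml_min=100.0)

    def test_zero_field_dynamic_pressure(self, bifurcation_mask):
        f = FlowField(u=np.zeros((bifurcation_mask.shape[0] + 1,
                                  bifurcation_mask.shape[1])),
                      v=np.zeros((bifurcation_mask.shape[0],
                                  bifurcation_mask.shape[1] + 1)),
                      p=np.zeros(bifurcation_mask.shape), time=0.0,
                      mask=bifurcation_mask)
        q = f.dynamic_pressure()
        assert np.nanmax(q) == 0.0
        w = wss_with(f, bifurcation_mask, 1e-3)
        assert np.allclose(w.tau, 0.0)


class TestPulsatile:
    def test_constant_waveform_reduces_to_steady(self):
        spec = BifurcationSpec(branch_length=0.0, trunk_length=6e-3)
        mask = rasterize(spec, 2e-3 / 16)
        cfg = FlowConfig(n_cycles=2)
        wf = make_waveform(q_forward=2.0, q_reverse=2.0)
        snaps, info = solve_pulsatile(mask, wf, cfg, snapshot_times=(0.24,))
        steady = solve_steady(mask, FlowConfig(), Q_ml_min=2.0)
        us, _ = steady.center_velocity()
        up, _ = snaps[0].center_velocity()
        assert np.max(np.abs(up - us)) / np.max(np.abs(us)) < 0.005

    def test_womersley_amplitude_and_phase(self):
        """Centerline oscillation against the plane-channel closed form
        (alpha ~ 3.6 at the default fluid and 0.48 s period)."""
        spec = BifurcationSpec(branch_length=0.0, trunk_length=16e-3)
        mask = rasterize(spec, 2e-3 / 32)
        wf = sinusoid_waveform(2.0, period=0.48, mean=0.0)
        cfg = FlowConfig(n_cycles=4)
        i_mid, j_mid = mask.shape[0] // 2, mask.shape[1] // 2
        snaps, info = solve_pulsatile(mask, wf, cfg, snapshot_times=(0.12,),
                                      record_centerline=(i_mid, j_mid))
        t, u = info["centerline"]
        om = 2 * np.pi / wf.period
        c = 2 * np.mean(u * np.exp(-1j * om * t))
        nu, a = 1e-6, 1e-3
        alpha = a * np.sqrt(om / nu)
        assert alpha == pytest.approx(3.6, abs=0.1)
        gam = np.sqrt(1j * om / nu)
        q0 = (2.0 * ML_PER_MIN) / 2e-3
        C = -1j * q0 / (2 * a - 2 * np.tanh(gam * a) / gam)
        # the recorded u-face sits half a cell off the centerline
        y_off = mask.origin[1] + mask.spacing * j_mid
        u_hat = C * (1 - np.cosh(gam * y_off) / np.cosh(gam * a))
        assert np.abs(c) == pytest.approx(np.abs(u_hat), rel=0.10)
        dphi = np.angle(c / u_hat)
        assert abs(dphi) < 0.1 * np.pi

    def test_mass_conserved_at_snapshots(self):
        mask_spec = BifurcationSpec()
        mask = rasterize(mask_spec, 0.25e-3)
        cfg = FlowConfig(n_cycles=2)
        snaps, _ = solve_pulsatile(mask, make_waveform(), cfg,
                                   snapshot_times=(0.07, 0.24))
        for s in snaps:
            qin, qout = s.flux_in(), s.flux_out()
            scale = max(abs(qin), (2.0 * ML_PER_MIN) / 2e-3)
            assert abs(qin - qout) / scale < 0.01

    def test_flow_reversal_creates_recirculation(self):
        """While the flow reverses (Q crossing zero on its way to the
        negative peak) the junction carries counter-flowing regions: both
        signs of u coexist near the apex; by the maximum-negative-flow
        phase (t = 0.24 s) the whole junction runs backward."""
        mask = rasterize(BifurcationSpec(), 0.25e-3)
        cfg = FlowConfig(n_cycles=3)
        wf = make_waveform()
        t_dense = np.linspace(0, wf.period, 481)
        q = wf.rate(t_dense)
        t_rev = float(t_dense[np.where(np.diff(np.sign(q)))[0][0]])
        snaps, _ = solve_pulsatile(mask, wf, cfg,
                                   snapshot_times=(round(t_rev, 3), 0.24))
        x, y = mask.cell_centers()
        X, Y = np.meshgrid(x, y, indexing="ij")
        apex = (np.hypot(X - 10e-3, Y) < 3e-3) & mask.fluid_mask()
        uc, _ = snaps[0].center_velocity()
        assert (uc[apex] > 1e-4).any() and (uc[apex] < -1e-4).any()
        uc24, _ = snaps[1].center_velocity()
        assert np.mean(uc24[apex] < 0) > 0.95
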