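"""Disc-magnet field: closed form, loop-superposition oracle, forces."""

import numpy as np
import pytest

from pvtarget.magnet import (MU_0, DiscMagnet, MagnetDomainError,
                             ParticleMagnetics, axial_Bz, axial_dBz_dz,
                             field_at, gradient_at, magnetophoretic_force,
                             sample_field_on_mask)


class TestAxialField:
    @pytest.mark.parametrize("z_mm, expected_T", [
        (0.4, 0.4015),   # the targeting gap: prints as 0.4 T
        (0.0, 0.4993),
        (1.0, 0.2696),
    ])
    def test_closed_form_values(self, magnet, z_mm, expected_T):
        assert axial_Bz(magnet, z_mm * 1e-3) == pytest.approx(expected_T, abs=5e-5)

    def test_rounds_to_printed_value(self, magnet):
        assert round(axial_Bz(magnet, 0.4e-3), 1) == 0.4

    def test_far_field_vanishes(self, magnet):
        assert axial_Bz(magnet, 1.0) < 1e-6

    def test_strictly_decreasing(self, magnet):
        z = np.linspace(0.0, 20e-3, 400)
        bz = axial_Bz(magnet, z)
        assert np.all(np.diff(bz) < 0)

    def test_bounded_by_remanence(self, magnet):
        z = np.linspace(0.0, 50e-3, 100)
        bz = axial_Bz(magnet, z)
        assert np.all(bz > 0) and np.all(bz < magnet.Br)

    def test_negative_z_rejected(self, magnet):
        with pytest.raises(MagnetDomainError):
            axial_Bz(magnet, -1e-4)

    def test_derivative_matches_sympy(self, magnet):
        """Closed-form dBz/dz against symbolic differentiation."""
        import sympy as sp

        z, Br, R, D = sp.symbols("z Br R D", positive=True)
        expr = Br / 2 * ((D + z) / sp.sqrt(R**2 + (D + z) ** 2)
                         - z / sp.sqrt(R**2 + z**2))
        dexpr = sp.lambdify(z, sp.diff(expr, z).subs(
            {Br: magnet.Br, R: magnet.R, D: magnet.D}))
        for zv in (0.1e-3, 0.4e-3, 1.0e-3, 5.0e-3):
            assert axial_dBz_dz(magnet, zv) == pytest.approx(
                float(dexpr(zv)), rel=1e-10)

    def test_small_thickness_limit_is_single_loop(self):
        """D -> 0 at fixed Br*D approaches the single-current-loop field."""
        D = 1e-7
        BrD = 1.3 * 2.4e-3
        m = DiscMagnet(Br=BrD / D, R=2e-3, D=D)
        z = 1.0e-3
        loop = BrD / MU_0 * MU_0 * m.R**2 / (2 * (m.R**2 + z**2) ** 1.5)
        assert axial_Bz(m, z) == pytest.approx(loop, rel=1e-4)


class TestOffAxisField:
    def test_on_axis_reduction(self, magnet, rng):
        """Loop superposition reduces to the closed form on the axis."""
        z = rng.uniform(1e-5, 20e-3, 100)
        pts = np.column_stack([np.zeros_like(z), -z])
        B = field_at(magnet, pts)
        assert np.allclose(np.abs(B[:, 1]), axial_Bz(magnet, z), rtol=1e-6)
        assert np.allclose(B[:, 0], 0.0, atol=1e-12)

    def test_axisymmetry(self, magnet):
        for r in (0.5e-3, 2e-3, 5e-3):
            Bp = field_at(magnet, (r, -0.4e-3))
            Bm = field_at(magnet, (-r, -0.4e-3))
            assert np.linalg.norm(Bp) == pytest.approx(np.linalg.norm(Bm),
                                                       rel=1e-12)

    def test_off_axis_weaker_than_on_axis(self, magnet):
        Bon = np.linalg.norm(field_at(magnet, (0.0, -0.4e-3)))
        Boff = np.linalg.norm(field_at(magnet, (5e-3, -0.4e-3)))
        assert Boff < Bon

    def test_against_midpoint_loop_oracle(self, magnet):
        """Independent oracle: brute-force midpoint-rule loop stack."""
        from scipy.special import ellipe, ellipk

        def oracle(r, z, n=2000):
            M = magnet.Br / MU_0
            zeta = (np.arange(n) + 0.5) * magnet.D / n
            I = M * magnet.D / n
            a = magnet.R
            dz = z + zeta
            d2 = (a + r) ** 2 + dz**2
            m_ = np.clip(4 * a * r / d2, 0, 1 - 1e-15)
            K, E = ellipk(m_), ellipe(m_)
            near = (a - r) ** 2 + dz**2
            pref = MU_0 * I / (2 * np.pi * np.sqrt(d2))
            Bz = np.sum(pref * (K + (a**2 - r**2 - dz**2) / near * E))
            if r == 0:
                return 0.0, Bz
            Br_ = np.sum(pref * dz / r * (-K + (a**2 + r**2 + dz**2) / near * E))
            return Br_, Bz

        for r, z in [(1e-3, 0.4e-3), (3e-3, 1e-3), (5e-3, 0.4e-3)]:
            B = field_at(magnet, (r, -z))
            br_o, bz_o = oracle(r, z)
            assert np.hypot(B[0], B[1]) == pytest.approx(
                np.hypot(br_o, bz_o), rel=1e-4)

    def test_inside_magnet_rejected(self, magnet):
        with pytest.raises(MagnetDomainError):
            field_at(magnet, (0.0, 1e-3))  # inside the body (axis = -y)


class TestGradient:
    def test_on_axis_matches_analytic(self, magnet):
        for z in (0.4e-3, 1e-3, 3e-3):
            G = gradient_at(magnet, (0.0, -z))
            # d(B_y)/dy on the -y axis equals the axial derivative
            assert G[1, 1] == pytest.approx(axial_dBz_dz(magnet, z), rel=1e-4)

    def test_far_field_gradient_vanishes(self, magnet):
        G = gradient_at(magnet, (0.0, -1.0))
        assert np.max(np.abs(G)) < 1e-3

    def test_axial_derivative_negative(self, magnet):
        z = np.linspace(1e-5, 20e-3, 50)
        assert np.all(axial_dBz_dz(magnet, z) < 0)


class TestForce:
    def setup_method(self):
        self.p = ParticleMagnetics(magnetic_volume=1e-22, chi=1e-4, Msat=4.8e5)

    def test_zero_field_zero_force(self):
        F = magnetophoretic_force(np.zeros(2), np.zeros((2, 2)), self.p)
        assert np.allclose(F, 0.0)

    def test_linear_in_volume_below_saturation(self, magnet):
        B = field_at(magnet, (1e-3, -1e-3))
        G = gradient_at(magnet, (1e-3, -1e-3))
        p2 = ParticleMagnetics(magnetic_volume=2e-22, chi=1e-4, Msat=4.8e5)
        F1 = magnetophoretic_force(B, G, self.p)
        F2 = magnetophoretic_force(B, G, p2)
        assert np.allclose(F2, 2.0 * F1, rtol=1e-12)

    def test_on_axis_force_points_toward_magnet(self, magnet):
        """Attractive along the axis for any gap (sign of Bz * dBz/dz)."""
        for z in (0.2e-3, 1e-3, 5e-3):
            B = field_at(magnet, (0.0, -z))
            G = gradient_at(magnet, (0.0, -z))
            F = magnetophoretic_force(B, G, self.p)
            assert F[1] > 0  # magnet sits toward +y

    def test_saturation_caps_magnetization(self, magnet):
        B = field_at(magnet, (0.0, -0.4e-3))
        G = gradient_at(magnet, (0.0, -0.4e-3))
        lo = ParticleMagnetics(magnetic_volume=1e-22, chi=20.0, Msat=4.8e5)
        hi = ParticleMagnetics(magnetic_volume=1e-22, chi=40.0, Msat=4.8e5)
        # both are saturated at 0.4 T, so doubling chi changes nothing
        assert np.allclose(magnetophoretic_force(B, G, lo),
                           magnetophoretic_force(B, G, hi))

    def test_invalid_particle_rejected(self):
        with pytest.raises(ValueError):
            ParticleMagnetics(magnetic_volume=-1e-22)
        with pytest.raises(ValueError):
            ParticleMagnetics(magnetic_volume=1e-22, chi=-1.0)


class TestSampleField:
    def test_field_map_on_straight_mask(self, straight_mask_32):
        mask = straight_mask_32
        m = DiscMagnet(face_center=(8e-3, 1e-3 + 0.4e-3), axis=(0.0, -1.0))
        fmap = sample_field_on_mask(m, mask)
        mags = fmap.magnitude
        # max |B| in the wall-adjacent row under the magnet footprint (the
        # rim enhancement keeps it off-axis but still nearest the face)
        pts = fmap.points
        top = pts[:, 1].max()
        imax = np.argmax(mags)
        assert pts[imax, 1] == pytest.approx(top, abs=1e-12)
        assert abs(pts[imax, 0] - m.face_center[0]) <= m.R
        assert np.all(np.isfinite(mags))

    def test_lumen_depth_variation_follows_closed_form(self, magnet):
        """Across the 2-mm lumen (gaps 0.4 -> 2.4 mm) the field drops to
        ~25% of its near-wall value, exactly as the axial formula gives."""
        b_near = axial_Bz(magnet, 0.4e-3)
        b_far = axial_Bz(magnet, 2.4e-3)
        drop = (b_near - b_far) / b_near
        assert drop == pytest.approx(0.749, abs=0.005)

    def test_magnet_inside_fluid_rejected(self, straight_mask_32):
        m = DiscMagnet(face_center=(8e-3, 0.0), axis=(0.0, -1.0))
        with pytest.raises(MagnetDomainError):
            sample_field_on_mask(m, straight_mask_32)
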