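"""D2Q9 MRT model: moment identities, kernel consistency, hydrodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimrl import kernels
from swimrl.grid import Block, NestedLattice, channel_wall_bc, make_outer_bc
from swimrl.lattice import (CS2, CX, CY, M, MINV, W, equilibrium, forcing_term,
                            macroscopic, relaxation_rates, viscous_stress)


class TestModelConstants:
    def test_weight_and_velocity_moments(self):
        assert W.sum() == pytest.approx(1.0, abs=1e-15)
        assert (W * CX).sum() == pytest.approx(0.0, abs=1e-15)
        assert (W * CY).sum() == pytest.approx(0.0, abs=1e-15)
        assert (W * CX * CX).sum() == pytest.approx(CS2, abs=1e-15)
        assert (W * CX * CY).sum() == pytest.approx(0.0, abs=1e-15)

    def test_moment_transform_invertible(self):
        assert np.allclose(M @ MINV, np.eye(9), atol=1e-12)

    def test_relaxation_rates_in_range(self):
        s = relaxation_rates(0.01)
        assert np.all(s >= 0)
        assert np.all(s < 2)
        with pytest.raises(ValueError):
            relaxation_rates(-0.2)


class TestEquilibrium:
    def test_rest_equilibrium_is_weights(self):
        assert np.allclose(equilibrium(1.0, 0.0, 0.0), W)

    def test_printed_value_axis_velocity(self):
        # rho=1, u=(0.1,0): f_eq for c=(1,0) = (1/9)(1+0.3+0.045-0.015)
        feq = equilibrium(1.0, 0.1, 0.0)
        assert feq[1] == pytest.approx((1 / 9) * (1 + 0.3 + 0.045 - 0.015),
                                       rel=1e-14)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.5, 2.0), st.floats(-0.15, 0.15), st.floats(-0.15, 0.15))
    def test_moment_identities(self, rho, ux, uy):
        feq = equilibrium(rho, ux, uy)
        assert feq.sum() == pytest.approx(rho, rel=1e-12)
        assert (feq * CX).sum() == pytest.approx(rho * ux, rel=1e-10, abs=1e-12)
        assert (feq * CY).sum() == pytest.approx(rho * uy, rel=1e-10, abs=1e-12)


class TestForcing:
    def test_zero_force_gives_zero(self):
        assert np.allclose(forcing_term(0.1, 0.0, 0.0, 0.0), 0.0)

    def test_printed_value(self):
        F = forcing_term(0.0, 0.0, 1.0, 0.0)
        assert F[1] == pytest.approx(1 / 3, rel=1e-14)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-0.1, 0.1), st.floats(-0.1, 0.1),
           st.floats(-1, 1), st.floats(-1, 1))
    def test_force_moments(self, ux, uy, gx, gy):
        F = forcing_term(ux, uy, gx, gy)
        assert F.sum() == pytest.approx(0.0, abs=1e-12)
        assert (F * CX).sum() == pytest.approx(gx, rel=1e-10, abs=1e-12)
        assert (F * CY).sum() == pytest.approx(gy, rel=1e-10, abs=1e-12)


class TestMacroscopic:
    def test_rest_equilibrium_density_two(self):
        f = equilibrium(2.0, 0.0, 0.0)
        rho, ux, uy, p = macroscopic(f)
        assert rho == pytest.approx(2.0)
        assert ux == pytest.approx(0.0)
        assert p == pytest.approx(2.0 / 3.0)

    def test_half_force_shift(self):
        f = equilibrium(1.0, 0.0, 0.0)
        rho, ux, uy, p = macroscopic(f, gx=0.1)
        assert ux == pytest.approx(0.05)

    def test_weights_are_unit_density(self):
        rho, *_ = macroscopic(W.copy())
        assert rho == pytest.approx(1.0)

    def test_negative_density_aborts(self):
        with pytest.raises(FloatingPointError):
            macroscopic(-W)


class TestKernelAgainstMatrixRoute:
    def _reference_step(self, f, gx, gy, s):
        """Plain-matrix MRT collide+stream (Eqs as printed), periodic."""
        ny, nx = f.shape[1:]
        rho = f.sum(0)
        ux = ((f * CX[:, None, None]).sum(0) + 0.5 * gx) / rho
        uy = ((f * CY[:, None, None]).sum(0) + 0.5 * gy) / rho
        feq = equilibrium(rho, ux, uy)
        F = forcing_term(ux, uy, gx, gy)
        flat = (f - feq).reshape(9, -1)
        post = f.reshape(9, -1) - (MINV @ (np.diag(s) @ (M @ flat)))
        post += MINV @ ((np.eye(9) - np.diag(s) / 2) @ (M @ F.reshape(9, -1)))
        post = post.reshape(9, ny, nx)
        out = np.empty_like(post)
        for i in range(9):
            out[i] = np.roll(np.roll(post[i], CY[i], axis=0), CX[i], axis=1)
        return out

    def test_one_step_matches_reference(self, rng):
        ny, nx = 12, 14
        ux = 0.05 * rng.standard_normal((ny, nx))
        uy = 0.05 * rng.standard_normal((ny, nx))
        rho = 1.0 + 0.02 * rng.standard_normal((ny, nx))
        f = equilibrium(rho, ux, uy) * (1 + 0.01 * rng.standard_normal((9, ny, nx)))
        gx = 1e-3 * rng.standard_normal((ny, nx))
        gy = 1e-3 * rng.standard_normal((ny, nx))
        s = relaxation_rates(0.02)
        blk = Block((0, 0), (ny, nx), 1.0, 0.02)
        blk.f[:] = f
        blk.gx[:] = gx
        blk.gy[:] = gy
        blk.step()
        ref = self._reference_step(f, gx, gy, s)
        assert np.allclose(blk.f, ref, atol=1e-13)


class TestHydrodynamics:
    def test_uniform_state_is_fixed_point(self):
        blk = Block((0, 0), (16, 16), 1.0, 0.05)
        blk.set_uniform(1.0, 0.07, -0.03)
        f0 = blk.f.copy()
        lat = NestedLattice([blk])
        for _ in range(20):
            lat.step()
        assert np.allclose(blk.f, f0, atol=1e-14)

    def test_mass_conserved_in_periodic_box(self, rng):
        blk = Block((0, 0), (32, 32), 1.0, 0.02)
        ux = 0.03 * rng.standard_normal((32, 32))
        blk.f[:] = equilibrium(np.ones((32, 32)), ux, -ux.T)
        m0 = blk.f.sum()
        lat = NestedLattice([blk])
        for _ in range(200):
            lat.step()
        assert abs(blk.f.sum() - m0) / m0 < 1e-12

    def test_taylor_green_decay_rate(self):
        n, nu, u0 = 64, 0.02, 0.02
        blk = Block((0, 0), (n, n), 1.0, nu)
        k = 2 * np.pi / n
        i = np.arange(n)
        ux = u0 * np.cos(k * i)[None, :] * np.sin(k * i)[:, None]
        uy = -u0 * np.sin(k * i)[None, :] * np.cos(k * i)[:, None]
        blk.f[:] = equilibrium(np.ones((n, n)), ux, uy)
        nsteps = int(0.5 / (2 * nu * k**2))
        lat = NestedLattice([blk])
        for _ in range(nsteps):
            lat.step()
        _, uxm, uym, _ = blk.macroscopic()
        amp = np.sqrt(np.mean(uxm**2 + uym**2) / np.mean(ux**2 + uy**2))
        assert amp == pytest.approx(np.exp(-2 * nu * k**2 * nsteps), rel=0.01)

    def test_poiseuille_profile(self):
        n, nu, g = 21, 0.05, 1e-6
        s_nu = 1.0 / (3 * nu + 0.5)
        s_q = 1.0 / ((3.0 / 16.0) / (1.0 / s_nu - 0.5) + 0.5)
        blk = Block((0, 0), (n, 8), 1.0, nu, s_q=s_q)
        blk.gx[:] = g
        lat = NestedLattice([blk], bc=channel_wall_bc())
        for _ in range(20000):
            lat.step()
        _, ux, _, _ = blk.macroscopic()
        y = np.arange(n)
        ua = g / (2 * nu) * (y + 0.5) * (n - 0.5 - y)
        assert np.max(np.abs(ux[:, 4] - ua)) / ua.max() < 0.01

    def test_second_order_spatial_convergence(self):
        errs = []
        for n in (32, 64):
            nu, u0 = 0.02, 0.02
            blk = Block((0, 0), (n, n), 1.0, nu * n / 32)  # same physical nu
            k = 2 * np.pi / n
            i = np.arange(n)
            ux = u0 * np.cos(k * i)[None, :] * np.sin(k * i)[:, None]
            uy = -u0 * np.sin(k * i)[None, :] * np.cos(k * i)[:, None]
            blk.f[:] = equilibrium(np.ones((n, n)), ux, uy)
            nu_l = nu * n / 32
            nsteps = int(0.3 / (2 * nu_l * k**2))
            lat = NestedLattice([blk])
            for _ in range(nsteps):
                lat.step()
            dec = np.exp(-2 * nu_l * k**2 * nsteps)
            _, uxm, uym, _ = blk.macroscopic()
            err = np.sqrt(np.mean((uxm - ux * dec) ** 2 +
                                  (uym - uy * dec) ** 2)) / u0
            errs.append(err)
        ratio = errs[0] / errs[1]
        assert 3.5 < ratio < 4.5

    def test_viscous_stress_linear_shear(self):
        # steady Kolmogorov-like shear maintained by a body force
        n, nu = 48, 0.05
        blk = Block((0, 0), (n, 8), 1.0, nu)
        k = 2 * np.pi / n
        j = np.arange(n)
        blk.gx[:] = (2 * nu * 1e-5 / k * k**2 *
                     np.sin(k * j))[:, None] * np.ones((1, 8))
        lat = NestedLattice([blk])
        for _ in range(6000):
            lat.step()
        sxx, sxy, syy = viscous_stress(blk.f, blk.s, blk.gx, blk.gy)
        _, ux, _, _ = blk.macroscopic()
        dudy = np.gradient(ux[:, 4])
        # sigma_xy = rho nu du/dx (Newtonian)
        mask = np.abs(dudy) > 0.3 * np.abs(dudy).max()
        ratio = sxy[:, 4][mask] / (nu * dudy[mask])
        assert np.allclose(ratio, 1.0, atol=0.02)

    def test_stress_tensor_symmetric_zero_at_equilibrium(self):
        blk = Block((0, 0), (8, 8), 1.0, 0.02)
        blk.set_uniform(1.0, 0.05, 0.01)
        sxx, sxy, syy = viscous_stress(blk.f, blk.s)
        assert np.allclose(sxx, 0.0, atol=1e-14)
        assert np.allclose(sxy, 0.0, atol=1e-14)


class TestOuterBC:
    def test_quiescent_domain_stays_at_rest(self):
        blk = Block((0, 0), (16, 20), 1.0, 0.02)
        lat = NestedLattice([blk], bc=make_outer_bc(0.0))
        for _ in range(50):
            lat.step()
        _, ux, uy, _ = blk.macroscopic()
        assert np.abs(ux).max() < 1e-14
        assert np.abs(uy).max() < 1e-14

    def test_uniform_inflow_empty_domain_reaches_free_stream(self):
        blk = Block((0, 0), (24, 40), 1.0, 0.02)
        blk.set_uniform(1.0, 0.0, 0.0)
        lat = NestedLattice([blk], bc=make_outer_bc(0.05))
        for _ in range(3000):
            lat.step()
        _, ux, uy, _ = blk.macroscopic()
        assert np.abs(ux - 0.05).max() < 1e-6
        assert np.abs(uy).max() < 1e-6

    def test_mass_flux_balance_at_steady_state(self):
        blk = Block((0, 0), (24, 40), 1.0, 0.02)
        blk.set_uniform(1.0, 0.05, 0.0)
        lat = NestedLattice([blk], bc=make_outer_bc(0.05))
        for _ in range(2000):
            lat.step()
        rho, ux, _, _ = blk.macroscopic()
        influx = (rho[:, 0] * ux[:, 0]).sum()
        outflux = (rho[:, -1] * ux[:, -1]).sum()
        assert abs(influx - outflux) / influx < 0.005
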