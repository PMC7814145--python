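"""Swimmer geometry, waveform blending and midline kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimrl.body import (
    BodyGeometry,
    blend_poly,
    build_markers,
    deformation_momentum,
    half_thickness,
    make_halfcycle_chain,
    mass_properties,
    midline_pose,
    momentum_correct,
    solve_waveform,
)

TROUT = BodyGeometry(kind="trout")
EEL = BodyGeometry(kind="anguilliform")


class TestHalfThickness:
    @pytest.mark.parametrize(
        "geom, s, expected, tol",
        [
            (TROUT, 0.0, 0.0, 1e-12),
            (TROUT, 1.0, 0.0, 1e-4),  # printed coefficients sum to 0.0000
            (TROUT, 0.25, 0.2610 * 0.5 - 0.3112 * 0.25 + 0.1371 * 0.25**2
             - 0.0791 * 0.25**3 - 0.0078 * 0.25**4, 1e-12),
            (EEL, 0.95, 0.01, 1e-12),  # tail-taper start has w_t half-width
            (EEL, 0.0, 0.0, 1e-12),
            (EEL, 1.0, 0.0, 1e-12),
        ],
    )
    def test_profile_values(self, geom, s, expected, tol):
        assert half_thickness(s, geom) == pytest.approx(expected, abs=tol)

    def test_profile_nonnegative_and_continuous(self):
        s = np.linspace(0, 1, 2001)
        for geom in (TROUT, EEL):
            d = half_thickness(s, geom)
            assert np.all(d >= 0)
            assert np.abs(np.diff(d)).max() < 0.02  # no jumps at piece joints

    def test_domain_error(self):
        with pytest.raises(ValueError):
            half_thickness(1.2, TROUT)


class TestWaveform:
    def test_endpoint_constraints_to_machine_precision(self):
        lam_prev, lam = 0.8, 1.3
        c = solve_waveform(lam_prev, lam)
        dc = c[1:] * np.arange(1, 6)
        ddc = dc[1:] * np.arange(1, 5)
        half = lam / 2

        def ev(co, z):
            return np.polyval(co[::-1], z)

        assert ev(c, 0.0) == pytest.approx(1.0, abs=1e-12)
        assert ev(c, half) == pytest.approx(-1.0, abs=1e-12)
        assert ev(dc, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert ev(dc, half) == pytest.approx(0.0, abs=1e-12)
        assert ev(ddc, 0.0) == pytest.approx(-(2 * np.pi / lam_prev) ** 2, rel=1e-12)
        assert ev(ddc, half) == pytest.approx((2 * np.pi / lam) ** 2, rel=1e-12)

    def test_quarter_point_against_independent_solve(self):
        # independent oracle: assemble and solve the 6x6 endpoint system here
        lam = 1.0
        half = lam / 2
        A = np.vander(np.array([0, half]), 6, increasing=True)
        d1 = np.array([[0, 1, 2 * z, 3 * z**2, 4 * z**3, 5 * z**4]
                       for z in (0, half)])
        d2 = np.array([[0, 0, 2, 6 * z, 12 * z**2, 20 * z**3]
                       for z in (0, half)])
        Msys = np.vstack([A, d1, d2])
        rhs = np.array([1, -1, 0, 0, -(2 * np.pi) ** 2, (2 * np.pi) ** 2])
        c_oracle = np.linalg.solve(Msys, rhs)
        c = solve_waveform(lam, lam)
        assert np.polyval(c[::-1], 0.25) == pytest.approx(
            np.polyval(c_oracle[::-1], 0.25), rel=1e-10)

    def test_constant_parameters_match_cosine_endpoint_data(self):
        lam = 1.0
        c = solve_waveform(lam, lam)
        z = np.array([0.0, lam / 2])
        cos = np.cos(2 * np.pi * z / lam)
        assert np.polyval(c[::-1], z) == pytest.approx(cos, abs=1e-12)

    def test_literal_printed_constraints_available(self):
        c = solve_waveform(1.0, 1.0, literal=True)
        assert np.polyval(c[::-1], 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_blend_continuous_at_junction(self):
        c = blend_poly(1.0, 1.0, amp_prev=0.6, amp_new=1.2)
        assert np.polyval(c[::-1], 0.0) == pytest.approx(0.6, abs=1e-12)
        assert np.polyval(c[::-1], 0.5) == pytest.approx(-1.2, abs=1e-12)

    def test_invalid_wavelengths(self):
        with pytest.raises(ValueError):
            solve_waveform(-1.0, 1.0)


class TestMidline:
    def test_zero_amplitude_is_straight(self):
        chain = make_halfcycle_chain([(1.0, 0.0, 1.0)] * 4)
        pose = midline_pose(0.7, chain, TROUT)
        assert np.allclose(pose.y, 0.0)
        assert np.allclose(pose.x, pose.s)
        assert np.allclose(pose.u, 0.0)
        assert np.allclose(pose.v, 0.0)

    def test_head_deflection_always_zero(self):
        chain = make_halfcycle_chain([(1.0, 1.2, 1.0)] * 6)
        for t in (0.1, 0.9, 1.7, 2.4):
            pose = midline_pose(t, chain, TROUT)
            assert pose.theta_l[0] == 0.0

    def test_arc_length_preserved_at_large_amplitude(self):
        th = np.deg2rad(160.0)
        chain = make_halfcycle_chain([(1.0, th, 1.0)] * 8)
        for t in (1.3, 2.0, 2.7):
            pose = midline_pose(t, chain, TROUT, n_s=401)
            arclen = np.sum(np.hypot(np.diff(pose.x), np.diff(pose.y)))
            assert arclen == pytest.approx(1.0, rel=1e-3)

    def test_tail_alternates_and_is_periodic(self):
        # constant (T, lambda): the tail trace must alternate sign every
        # half cycle and repeat with period T after the wave fills the body
        th = np.deg2rad(60.0)
        chain = make_halfcycle_chain([(1.0, th, 1.0)] * 14)
        t0 = 3.25
        y1 = midline_pose(t0, chain, TROUT).y[-1]
        y2 = midline_pose(t0 + 0.5, chain, TROUT).y[-1]
        y3 = midline_pose(t0 + 1.0, chain, TROUT).y[-1]
        assert y1 * y2 < 0
        assert y3 == pytest.approx(y1, rel=1e-6, abs=1e-9)

    def test_tail_trace_c2_across_cycle_boundaries(self):
        # sample the tail angle finely across a junction: the matching
        # conditions make value/slope/curvature continuous
        th = np.deg2rad(90.0)
        chain = make_halfcycle_chain([(1.0, th, 1.0)] * 8)
        ts = np.linspace(1.95, 2.05, 41)
        ytail = [midline_pose(t, chain, TROUT).y[-1] for t in ts]
        d2 = np.diff(ytail, 2)
        assert np.abs(d2).max() < 5e-4  # smooth second difference

    def test_time_outside_span_raises(self):
        chain = make_halfcycle_chain([(1.0, 0.5, 1.0)] * 2)
        with pytest.raises(ValueError):
            midline_pose(5.0, chain, TROUT)


class TestMassProperties:
    def test_straight_mass_equals_quadrature_oracle(self):
        from scipy.integrate import quad
        pose = midline_pose(0.2, make_halfcycle_chain([(1.0, 0.0, 1.0)]), TROUT,
                            n_s=801)
        m, rc, Iz = mass_properties(pose, TROUT)
        m_oracle, _ = quad(lambda s: 2 * float(half_thickness(s, TROUT)), 0, 1,
                           limit=200)
        # Simpson on the sqrt-singular head limits the attainable agreement
        assert m == pytest.approx(m_oracle, rel=5e-4)
        assert Iz > 0

    def test_translation_invariance_of_inertia(self):
        chain = make_halfcycle_chain([(1.0, 0.8, 1.0)] * 4)
        pose = midline_pose(1.2, chain, TROUT)
        _, _, I1 = mass_properties(pose, TROUT)
        pose.x = pose.x + 3.7
        pose.y = pose.y - 1.1
        _, _, I2 = mass_properties(pose, TROUT)
        assert I2 == pytest.approx(I1, rel=1e-12)

    def test_reflection_symmetry(self):
        chain = make_halfcycle_chain([(1.0, 0.8, 1.0)] * 4)
        pose = midline_pose(1.2, chain, TROUT)
        m1, _, I1 = mass_properties(pose, TROUT)
        pose.y = -pose.y
        m2, _, I2 = mass_properties(pose, TROUT)
        assert m2 == pytest.approx(m1, rel=1e-14)
        assert I2 == pytest.approx(I1, rel=1e-14)


class TestMomentumCorrection:
    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10**6))
    def test_random_smooth_deformation_momentum_removed(self, seed):
        r = np.random.default_rng(seed)
        chain = make_halfcycle_chain([(1.0, 1.0, 1.0)] * 4)
        pose = midline_pose(r.uniform(0.2, 1.8), chain, TROUT)
        # superpose random low-order polynomial velocity noise
        pose.u = pose.u + np.polyval(r.normal(size=3) * 0.1, pose.s)
        pose.v = pose.v + np.polyval(r.normal(size=3) * 0.1, pose.s)
        fixed = momentum_correct(pose, TROUT)
        P, Lz = deformation_momentum(fixed, TROUT)
        assert np.abs(P).max() < 1e-10
        assert abs(Lz) < 1e-10

    def test_uniform_offset_removed_exactly(self):
        chain = make_halfcycle_chain([(1.0, 0.0, 1.0)])
        pose = midline_pose(0.3, chain, TROUT)
        pose.u = pose.u + 0.37
        fixed = momentum_correct(pose, TROUT)
        assert np.allclose(fixed.u, 0.0, atol=1e-13)


class TestMarkers:
    def test_marker_spacing_bounded_by_grid(self):
        chain = make_halfcycle_chain([(1.0, 1.2, 1.0)] * 4)
        pose = midline_pose(1.1, chain, TROUT, n_s=401)
        dx = 0.01
        X, U = build_markers(pose, TROUT, dx)
        seg = np.linalg.norm(np.diff(np.vstack([X, X[:1]]), axis=0), axis=1)
        assert seg.max() <= 1.5 * dx

    def test_total_arc_length_matches_polygon(self):
        from swimrl.ib import polygon_weights
        chain = make_halfcycle_chain([(1.0, 0.0, 1.0)])
        pose = midline_pose(0.2, chain, TROUT, n_s=401)
        X, _ = build_markers(pose, TROUT, 0.01)
        ds0, normals = polygon_weights(X)
        seg = np.linalg.norm(np.diff(np.vstack([X, X[:1]]), axis=0), axis=1)
        assert ds0.sum() == pytest.approx(seg.sum(), rel=1e-3)
        assert np.allclose(np.linalg.norm(normals, axis=1), 1.0)
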