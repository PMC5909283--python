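import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tma_dearray.ellipse_fit import (
    Ellipse,
    FitConfig,
    ellipse_energy,
    ellipse_energy_gradient,
    ellipse_norm2,
    fit_all,
    fit_single,
    logistic_weight,
    logistic_weight_deriv,
)
from tma_dearray.io_preprocess import IntensityImage, extract_patch
from conftest import render_disk, render_ellipse


def make_patch(pixels, center=None, radius=None):
    img = IntensityImage(np.asarray(pixels, dtype=float))
    if center is None:
        center = ((img.width - 1) / 2, (img.height - 1) / 2)
    if radius is None:
        radius = (min(img.width, img.height) - 1) / 2
    return extract_patch(img, center, radius)


class TestEllipseNorm:
    def test_center_is_zero(self):
        e = Ellipse(3.0, 4.0, 10.0, 5.0, 0.3)
        assert ellipse_norm2(3.0, 4.0, e) == pytest.approx(0.0)

    def test_major_vertex_is_one(self):
        e = Ellipse(0.0, 0.0, 10.0, 5.0, 0.3)
        x = 10.0 * np.cos(0.3)
        y = 10.0 * np.sin(0.3)
        assert ellipse_norm2(x, y, e) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x=st.floats(-50, 50),
        y=st.floats(-50, 50),
        a=st.floats(2, 30),
        b=st.floats(2, 30),
        theta=st.floats(-np.pi, np.pi),
    )
    def test_rotation_equivariance(self, x, y, a, b, theta):
        """Rotating the query point and the ellipse together leaves the
        ellipse-induced norm unchanged (and it is never negative)."""
        phi = 0.7
        e = Ellipse(0.0, 0.0, a, b, theta)
        e_rot = Ellipse(0.0, 0.0, a, b, theta + phi)
        c, s = np.cos(phi), np.sin(phi)
        xr, yr = c * x - s * y, s * x + c * y
        t = float(ellipse_norm2(x, y, e))
        assert t >= 0.0
        assert float(ellipse_norm2(xr, yr, e_rot)) == pytest.approx(t, rel=1e-9, abs=1e-9)

    def test_circle_reduces_to_euclidean(self, rng):
        r = 7.0
        for theta in (0.0, 0.4, -1.2):
            e = Ellipse(1.0, -2.0, r, r, theta)
            pts = rng.normal(0, 10, size=(50, 2))
            expected = ((pts[:, 0] - 1.0) ** 2 + (pts[:, 1] + 2.0) ** 2) / r**2
            got = ellipse_norm2(pts[:, 0], pts[:, 1], e)
            assert np.allclose(got, expected)


class TestLogisticWeight:
    def test_ring_limit_is_plus_one(self):
        assert logistic_weight(0.75, 1e-3) == pytest.approx(1.0, abs=1e-6)

    def test_core_limit_is_minus_one(self):
        assert logistic_weight(0.25, 1e-3) == pytest.approx(-1.0, abs=1e-6)

    def test_far_field_is_zero(self):
        assert logistic_weight(1e6, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_overflow_safe(self):
        t = np.array([-1e8, 0.0, 1e8])
        w = logistic_weight(t, 1e-4)
        assert np.all(np.isfinite(w))

    def test_derivative_matches_finite_difference(self):
        eps = 0.05
        ts = np.linspace(0.0, 2.0, 41)
        h = 1e-6
        fd = (logistic_weight(ts + h, eps) - logistic_weight(ts - h, eps)) / (2 * h)
        assert np.allclose(logistic_weight_deriv(ts, eps), fd, atol=1e-4)


class TestEllipseEnergy:
    def test_constant_patch_cancels(self):
        """Equal ring and core areas: J vanishes on a constant image."""
        patch = make_patch(np.full((61, 61), 5.0))
        e = Ellipse(30.0, 30.0, 12.0, 9.0, 0.4)
        J = ellipse_energy(patch, e, 0.05)
        assert abs(J) < 0.02 * 5.0

    def test_bright_inner_core_gives_minus_half_pi(self):
        """u = 1 on the inner ellipse, 0 outside: J -> -(1/ab)|Gamma'| = -pi/2."""
        e = Ellipse(40.0, 40.0, 20.0, 20.0, 0.0)
        # inner ellipse has axes a/sqrt(2): t <= 0.5 <=> inside Gamma'
        u = render_disk((81, 81), (40.0, 40.0), 20.0 / np.sqrt(2))
        patch = make_patch(u)
        J = ellipse_energy(patch, e, 0.01)
        # pixel sampling of the discontinuous integrand limits the agreement
        assert J == pytest.approx(-np.pi / 2, abs=0.1)

    def test_matched_beats_mismatched(self):
        u = render_disk((81, 81), (40.0, 40.0), 10.0)
        patch = make_patch(u)
        matched = Ellipse(40.0, 40.0, 10.0 * np.sqrt(2), 10.0 * np.sqrt(2), 0.0)
        mismatched = Ellipse(40.0, 40.0, 2 * 10.0 * np.sqrt(2), 2 * 10.0 * np.sqrt(2), 0.0)
        assert ellipse_energy(patch, matched, 0.05) < ellipse_energy(patch, mismatched, 0.05)

    def test_small_eps_converges_to_hard_indicator(self):
        """As eps -> 0 the smoothed energy approaches the brute-force
        indicator sum (1_Gamma - 2*1_Gamma') u."""
        rngl = np.random.default_rng(3)
        u = rngl.random((61, 61))
        patch = make_patch(u)
        e = Ellipse(30.0, 30.0, 14.0, 11.0, 0.5)
        xx, yy = patch.grid()
        t = ellipse_norm2(xx, yy, e)
        hard = np.where(t <= 1.0, 1.0, 0.0) - 2.0 * np.where(t <= 0.5, 1.0, 0.0)
        J_hard = float(np.sum(hard * patch.pixels) / (e.a * e.b))
        errs = [abs(ellipse_energy(patch, e, eps) - J_hard) for eps in (0.2, 0.05, 0.01)]
        assert errs[0] > errs[-1]
        assert errs[-1] < 0.02


class TestEnergyGradient:
    def test_matches_finite_differences(self):
        """Analytic gradient vs central differences on 100 random patches
        and ellipse configurations."""
        rngl = np.random.default_rng(7)
        h = 1e-4
        for _ in range(100):
            u = rngl.random((41, 41))
            patch = make_patch(u)
            e = Ellipse(
                20.0 + rngl.uniform(-3, 3),
                20.0 + rngl.uniform(-3, 3),
                rngl.uniform(8, 14),
                rngl.uniform(5, 8),
                rngl.uniform(-1.2, 1.2),
            )
            eps = rngl.uniform(0.03, 0.15)
            grad = ellipse_energy_gradient(patch, e, eps)
            v = e.as_vector()
            fd = np.empty(5)
            for i in range(5):
                vp, vm = v.copy(), v.copy()
                vp[i] += h
                vm[i] -= h
                fd[i] = (
                    ellipse_energy(patch, Ellipse(*vp), eps)
                    - ellipse_energy(patch, Ellipse(*vm), eps)
                ) / (2 * h)
            scale = max(1.0, np.abs(fd).max())
            assert np.allclose(grad, fd, atol=1e-4 * scale), (grad, fd)

    def test_constant_patch_position_gradient_vanishes(self):
        patch = make_patch(np.full((41, 41), 2.0))
        e = Ellipse(20.0, 20.0, 10.0, 10.0, 0.0)
        g = ellipse_energy_gradient(patch, e, 0.05)
        assert np.allclose(g[[0, 1, 4]], 0.0, atol=1e-6)

    def test_rotational_symmetry_kills_theta_gradient(self):
        u = render_disk((61, 61), (30.0, 30.0), 10.0)
        patch = make_patch(u)
        e = Ellipse(30.0, 30.0, 12.0, 12.0, 0.7)
        g = ellipse_energy_gradient(patch, e, 0.05)
        assert abs(g[4]) < 1e-8


class TestEnergyInvariance:
    def test_theta_plus_pi(self, rng):
        u = rng.random((41, 41))
        patch = make_patch(u)
        e1 = Ellipse(20.0, 20.0, 12.0, 7.0, 0.3)
        e2 = Ellipse(20.0, 20.0, 12.0, 7.0, 0.3 + np.pi)
        assert ellipse_energy(patch, e1, 0.05) == pytest.approx(
            ellipse_energy(patch, e2, 0.05)
        )

    def test_axis_swap_with_quarter_turn(self, rng):
        u = rng.random((41, 41))
        patch = make_patch(u)
        e1 = Ellipse(20.0, 20.0, 12.0, 7.0, 0.3)
        e2 = Ellipse(20.0, 20.0, 7.0, 12.0, 0.3 + np.pi / 2)
        assert ellipse_energy(patch, e1, 0.05) == pytest.approx(
            ellipse_energy(patch, e2, 0.05)
        )


class TestFitSingle:
    def test_recovers_disk(self):
        r = 15.0
        img = IntensityImage(render_disk((101, 101), (50.3, 49.6), r))
        cfg = FitConfig(r_core=r)
        patch = extract_patch(img, (50.0, 50.0), cfg.rho)
        init = Ellipse(50.0, 50.0, r, r, 0.0)
        res = fit_single(patch, init, cfg)
        assert res.accepted
        assert np.hypot(res.ellipse.x0 - 50.3, res.ellipse.y0 - 49.6) <= 0.5
        assert res.ellipse.a == pytest.approx(r * np.sqrt(2), rel=0.10)
        assert res.ellipse.b == pytest.approx(r * np.sqrt(2), rel=0.10)

    def test_recovers_rotation_of_elongated_core(self):
        theta = np.deg2rad(30.0)
        img = IntensityImage(render_ellipse((121, 121), (60.0, 60.0), 20.0, 10.0, theta))
        cfg = FitConfig(r_core=15.0)
        patch = extract_patch(img, (60.0, 60.0), cfg.rho)
        res = fit_single(patch, Ellipse(60.0, 60.0, 15.0, 15.0, 0.0), cfg)
        assert abs(res.ellipse.theta - theta) <= np.deg2rad(5.0)

    def test_fixed_point_at_optimum(self):
        r = 15.0
        img = IntensityImage(render_disk((101, 101), (50.0, 50.0), r))
        cfg = FitConfig(r_core=r)
        patch = extract_patch(img, (50.0, 50.0), cfg.rho)
        init = Ellipse(50.0, 50.0, r, r, 0.0)
        first = fit_single(patch, init, cfg)
        again = fit_single(patch, first.ellipse, cfg)
        assert np.hypot(again.ellipse.x0 - first.ellipse.x0, again.ellipse.y0 - first.ellipse.y0) < 0.2
        assert again.ellipse.a == pytest.approx(first.ellipse.a, abs=0.3)

    def test_monotone_descent(self):
        """The optimizer never increases the energy between accepted iterates."""
        from scipy.optimize import minimize

        img = IntensityImage(render_disk((101, 101), (52.0, 48.0), 15.0))
        cfg = FitConfig(r_core=15.0)
        patch = extract_patch(img, (50.0, 50.0), cfg.rho)
        trace = []

        def f(v):
            J = ellipse_energy(patch, Ellipse(*v), cfg.eps)
            return J, ellipse_energy_gradient(patch, Ellipse(*v), cfg.eps)

        def cb(v):
            trace.append(f(v)[0])

        minimize(
            f,
            np.array([50.0, 50.0, 15.0, 15.0, 0.0]),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": 100},
        )
        assert len(trace) >= 2
        assert all(b <= a + 1e-10 for a, b in zip(trace, trace[1:]))


class TestFitAll:
    def test_two_separated_disks_both_accepted(self):
        img = render_disk((151, 251), (60.0, 75.0), 15.0)
        img += render_disk((151, 251), (180.0, 75.0), 15.0)
        res = fit_all(IntensityImage(img), [(60, 75), (180, 75)], FitConfig(r_core=15.0))
        assert sum(r.accepted for r in res) == 2

    def test_duplicate_detection_keeps_one(self):
        img = IntensityImage(render_disk((151, 151), (75.0, 75.0), 15.0))
        res = fit_all(img, [(74.0, 75.0), (77.0, 75.0)], FitConfig(r_core=15.0))
        assert sum(r.accepted for r in res) == 1

    def test_elongated_streak_rejected(self):
        img = IntensityImage(render_ellipse((151, 151), (75.0, 75.0), 40.0, 10.0, 0.0))
        res = fit_all(img, [(75.0, 75.0)], FitConfig(r_core=15.0))
        assert not any(r.accepted for r in res)

    def test_undersized_and_oversized_rejected(self):
        cfg = FitConfig(r_core=15.0)
        small = IntensityImage(render_disk((151, 151), (75.0, 75.0), 7.5))
        big = IntensityImage(render_disk((201, 201), (100.0, 100.0), 30.0))
        assert not any(r.accepted for r in fit_all(small, [(75.0, 75.0)], cfg))
        assert not any(r.accepted for r in fit_all(big, [(100.0, 100.0)], cfg))
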