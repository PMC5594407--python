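"""Energy terms: closed forms, quadrature behavior, gradient oracles."""

import numpy as np
import pytest

from elastract.curves import Curve, curve_derivatives, resample_uniform
from elastract.energies import (e_data_odf, e_data_tensor, e_smooth,
                                grad_e_data_odf, grad_e_data_tensor,
                                grad_e_smooth)
from elastract.fields import ODFField, TensorField, sym_eigvals

from conftest import (bilinear_inverse_field, fd_curve_gradient, smooth_curve,
                      smooth_odf_field, trig_tensor_field)


def constant_field(M0, grid=(10, 10)):
    return TensorField(np.tile(np.asarray(M0, float), grid + (1, 1)))


def uniform_odf(grid=(8, 8), n_coeffs=5):
    co = np.zeros(grid + (n_coeffs,))
    co[..., 0] = 1.0
    return ODFField(co)


def hline(T=41, y=0.5):
    return Curve(np.column_stack([np.linspace(0.1, 0.9, T), np.full(T, y)]))


def vline(T=41, x=0.5):
    return Curve(np.column_stack([np.full(T, x), np.linspace(0.1, 0.9, T)]))


class TestTensorDataTerm:
    def test_identity_field_gives_one(self):
        f = constant_field(np.eye(2))
        for c in [hline(), vline(), smooth_curve(3)]:
            assert np.isclose(e_data_tensor(f, c), 1.0)

    def test_anisotropic_closed_form(self):
        f = constant_field(np.diag([1.0, 0.1]))
        assert np.isclose(e_data_tensor(f, hline()), 1.0)
        assert np.isclose(e_data_tensor(f, vline()), 10.0)

    def test_refinement_convergence(self):
        # the same analytic curve sampled at T and 2T-1 (identical
        # parameterization, doubled density)
        f = trig_tensor_field(seed=2)
        v = [e_data_tensor(f, smooth_curve(seed=9, T=T)) for T in (101, 201)]
        assert abs(v[1] - v[0]) / abs(v[0]) < 1e-3

    def test_lower_bound_inverse_max_eigenvalue(self):
        f = trig_tensor_field(seed=6)
        c = smooth_curve(seed=2)
        lam1, _ = sym_eigvals(f.interpolate_many(c.points))
        assert e_data_tensor(f, c) >= 1.0 / lam1.max() - 1e-12

    def test_speed_weighted_variant_scales_with_length(self):
        f = constant_field(np.eye(2))
        c = hline()
        assert np.isclose(e_data_tensor(f, c, speed_weighted=True), c.length())


class TestTensorDataGradient:
    def test_constant_isotropic_zero(self):
        f = constant_field(2.0 * np.eye(2))
        g = grad_e_data_tensor(f, smooth_curve(1))
        assert np.abs(g[3:-3]).max() < 1e-10

    def test_straight_line_along_dominant_axis_stationary(self):
        f = constant_field(np.diag([1.0, 0.1]))
        g = grad_e_data_tensor(f, hline())
        assert np.abs(g[3:-3]).max() < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        """Analytic gradient vs FD of the discrete energy, interior points.

        Fields whose inverse is bilinear make interpolation and the
        gradient caches exact, isolating the adjoint structure itself.
        """
        f = bilinear_inverse_field(seed=seed)
        c = smooth_curve(seed=seed + 50)
        ana = grad_e_data_tensor(f, c)
        fd = fd_curve_gradient(lambda cc: e_data_tensor(f, cc), c) / c.dt
        m = slice(3, len(c) - 3)
        err = np.abs(ana[m] - fd[m]).max() / np.abs(fd[m]).max()
        assert err < 1e-3

    def test_generic_smooth_field_within_cache_tolerance(self):
        # with generic fields the bilinear gradient cache is itself only
        # ~1e-2 accurate, and the gradient inherits that
        f = trig_tensor_field(seed=0)
        c = smooth_curve(seed=10)
        ana = grad_e_data_tensor(f, c)
        fd = fd_curve_gradient(lambda cc: e_data_tensor(f, cc), c) / c.dt
        m = slice(3, len(c) - 3)
        assert np.abs(ana[m] - fd[m]).max() / np.abs(fd[m]).max() < 1e-2


class TestSmoothness:
    def test_unit_segment(self):
        c = Curve(np.column_stack([np.linspace(0, 1, 31), np.full(31, 0.5)]))
        assert np.isclose(e_smooth(c), 1.0)

    def test_circle_length(self):
        t = np.linspace(0, 2 * np.pi, 2001)
        r = 0.3
        c = Curve(np.column_stack([0.5 + r * np.cos(t), 0.5 + r * np.sin(t)]))
        assert np.isclose(e_smooth(c), 2 * np.pi * r, rtol=1e-3)

    def test_resampling_invariance(self):
        c = smooth_curve(seed=4, T=150)
        c2 = Curve(resample_uniform(c.points, 97))
        assert abs(e_smooth(c) - e_smooth(c2)) / e_smooth(c) < 1e-3

    def test_straight_line_zero_gradient(self):
        g = grad_e_smooth(hline())
        assert np.abs(g).max() < 1e-10

    def test_circle_curvature_flow(self):
        t = np.linspace(0, np.pi, 400)
        r = 0.3
        c = Curve(np.column_stack([0.5 + r * np.cos(t), 0.5 + r * np.sin(t)]))
        g = grad_e_smooth(c)
        mags = np.hypot(g[:, 0], g[:, 1])[5:-5]
        assert np.allclose(mags, 1.0 / r, rtol=1e-3)
        # the gradient of length points away from the curvature center, so
        # that descent shrinks the curve (curve-shortening flow)
        radial = (c.points - [0.5, 0.5]) / r
        dots = np.einsum("ti,ti->t", g, radial)[5:-5]
        assert np.all(dots > 0)

    def test_matches_finite_differences(self):
        c = smooth_curve(seed=11)
        _, _, _, speed = curve_derivatives(c)
        ana = grad_e_smooth(c)
        fd = fd_curve_gradient(e_smooth, c) / (c.dt * speed[:, None])
        m = slice(3, len(c) - 3)
        assert np.abs(ana[m] - fd[m]).max() / np.abs(fd[m]).max() < 1e-2


class TestODFDataTerm:
    def test_uniform_field_constant_energy(self):
        f = uniform_odf()
        assert np.isclose(e_data_odf(f, hline()), -1.0 / (2 * np.pi))
        assert np.isclose(e_data_odf(f, smooth_curve(1)), -1.0 / (2 * np.pi))

    def test_peak_alignment_preferred(self):
        co = np.zeros((8, 8, 5))
        co[..., 0] = 1.0
        co[..., 1] = 0.8  # lobe along theta = 0
        f = ODFField(co)
        assert e_data_odf(f, hline()) < e_data_odf(f, vline())

    def test_refinement_convergence(self):
        f = smooth_odf_field(seed=3)
        v = [e_data_odf(f, smooth_curve(seed=12, T=T)) for T in (101, 201)]
        assert abs(v[1] - v[0]) / abs(v[0]) < 1e-3

    def test_lower_bound_minus_max_density(self):
        f = smooth_odf_field(seed=8)
        c = smooth_curve(seed=3)
        thetas = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        fmax = max(f.evaluate_many(np.tile(p, (360, 1)), thetas).max()
                   for p in c.points[::10])
        assert e_data_odf(f, c) >= -fmax - 1e-9


class TestODFDataGradient:
    def test_uniform_field_zero(self):
        g = grad_e_data_odf(uniform_odf(), smooth_curve(5))
        assert np.abs(g).max() < 1e-10

    def test_straight_line_through_aligned_lobe_stationary(self):
        co = np.zeros((8, 8, 5))
        co[..., 0] = 1.0
        co[..., 1] = 0.8
        f = ODFField(co)
        g = grad_e_data_odf(f, hline())
        assert np.abs(g[3:-3]).max() < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        f = smooth_odf_field(seed=seed)
        c = smooth_curve(seed=seed + 70)
        ana = grad_e_data_odf(f, c)
        fd = fd_curve_gradient(lambda cc: e_data_odf(f, cc), c) / c.dt
        m = slice(3, len(c) - 3)
        assert np.abs(ana[m] - fd[m]).max() / np.abs(fd[m]).max() < 1e-2
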