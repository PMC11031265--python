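"""Forward-operator correctness: oracles, adjointness, convergence."""

import numpy as np
import pytest

import xactring as xr
from xactring.forward import (
    ArcIntegralSeries,
    OperatorSpec,
    arc_integrals,
    assemble_dense,
    time_derivative,
)

from conftest import antialiased_disc, disc_arc_integral_closed_form


def _random_image(spec, seed=0):
    rng = np.random.default_rng(seed)
    return xr.SourceImage(rng.standard_normal(spec.grid.shape), spec.grid)


def _random_sinogram(spec, seed=1):
    rng = np.random.default_rng(seed)
    shape = (spec.ring.n_detectors, spec.time_axis.n_samples)
    return xr.Sinogram(rng.standard_normal(shape), spec.ring, spec.time_axis)


class TestArcIntegrals:
    def test_zero_image_gives_zero_series(self, tiny_spec):
        img = xr.SourceImage(np.zeros(tiny_spec.grid.shape), tiny_spec.grid)
        series = arc_integrals(img, tiny_spec)
        assert np.all(series.values == 0.0)

    def test_linearity_in_image(self, tiny_spec):
        img = _random_image(tiny_spec)
        s1 = arc_integrals(img, tiny_spec).values
        s3 = arc_integrals(
            xr.SourceImage(3.0 * img.values, tiny_spec.grid), tiny_spec
        ).values
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-13)

    def test_centered_disc_matches_closed_form(self):
        """Arc integrals of a disc agree with the circle-circle intersection angle."""
        grid = xr.make_grid(1e-2, 5e-5)
        a, A = 3e-3, 2.0
        img = antialiased_disc(grid, a, A)
        ring = xr.make_ring(5e-2, 2, 360.0)
        ta = xr.make_time_axis(grid, ring, 20e6)
        spec = OperatorSpec(grid, ring, ta, n_quadrature=400)
        series = arc_integrals(img, spec)
        vt = ring.sound_speed * ta.times
        exact = disc_arc_integral_closed_form(A, a, ring.radius, vt)
        assert np.max(np.abs(series.values[0] - exact)) < 0.02 * exact.max()

    def test_quadrature_convergence_is_monotone(self):
        """Doubling Nq monotonically shrinks the error on transversal arcs.

        Arcs grazing the disc edge (vt near |R +/- a|) are dominated by the
        pixel-level edge profile rather than quadrature, so the comparison
        stays at least 5 pixels away from the tangency radii.
        """
        grid = xr.make_grid(1e-2, 5e-5)
        a, A = 3e-3, 2.0
        img = antialiased_disc(grid, a, A)
        ring = xr.make_ring(5e-2, 2, 360.0)
        ta = xr.make_time_axis(grid, ring, 20e6)
        vt = ring.sound_speed * ta.times
        R, h = ring.radius, grid.spacing
        exact = disc_arc_integral_closed_form(A, a, R, vt)
        transversal = (np.abs(vt - (R - a)) > 5 * h) & (np.abs(vt - (R + a)) > 5 * h)
        errs = []
        for nq in (50, 100, 200, 400, 800):
            spec = OperatorSpec(grid, ring, ta, n_quadrature=nq)
            series = arc_integrals(img, spec)
            errs.append(np.max(np.abs(series.values[0] - exact)[transversal]))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:])), errs

    def test_mismatched_grid_rejected(self, tiny_spec):
        other = xr.make_grid(6e-3, 1e-3)
        img = xr.SourceImage(np.zeros(other.shape), other)
        with pytest.raises(ValueError):
            arc_integrals(img, tiny_spec)


class TestTimeDerivative:
    def _series(self, tiny_spec, values):
        return ArcIntegralSeries(values, tiny_spec.ring, tiny_spec.time_axis)

    def test_constant_series_differentiates_to_zero(self, tiny_spec):
        shape = (tiny_spec.ring.n_detectors, tiny_spec.time_axis.n_samples)
        sino = time_derivative(self._series(tiny_spec, np.full(shape, 4.2)))
        np.testing.assert_allclose(sino.values, 0.0, atol=1e-9)

    def test_ramp_differentiates_to_one(self, tiny_spec):
        ta = tiny_spec.time_axis
        ramp = np.tile(ta.times, (tiny_spec.ring.n_detectors, 1))
        sino = time_derivative(self._series(tiny_spec, ramp))
        np.testing.assert_allclose(sino.values, 1.0, rtol=1e-9)

    def test_sine_derivative_second_order_interior(self):
        ring = xr.make_ring(5e-2, 2, 360.0)
        omega = 2 * np.pi * 1e6
        errs = []
        for nt in (400, 800):
            ta = xr.TimeAxis(t0=0.0, dt=(100 / omega) / nt, n_samples=nt)
            t = ta.times
            series = ArcIntegralSeries(np.tile(np.sin(omega * t), (2, 1)), ring, ta)
            sino = time_derivative(series)
            interior = np.max(
                np.abs(sino.values[0, 1:-1] - omega * np.cos(omega * t[1:-1]))
            )
            errs.append(interior / omega)
        # halving dt shrinks the interior error ~4x (second order)
        assert errs[1] < errs[0] / 3.0

    def test_too_few_samples_rejected(self):
        ring = xr.make_ring(5e-2, 2, 360.0)
        with pytest.raises(ValueError):
            ta = xr.TimeAxis(t0=0.0, dt=1e-7, n_samples=2)


class TestOperatorPair:
    def test_forward_linearity(self, tiny_spec):
        h1, h2 = _random_image(tiny_spec, 1), _random_image(tiny_spec, 2)
        a, b = 2.5, -1.25
        combo = xr.SourceImage(a * h1.values + b * h2.values, tiny_spec.grid)
        lhs = xr.forward_apply(combo, tiny_spec).values
        rhs = (a * xr.forward_apply(h1, tiny_spec).values
               + b * xr.forward_apply(h2, tiny_spec).values)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_adjoint_dot_test(self, tiny_spec):
        """<M u, w> == <u, M^T w> to 1e-10 relative — definition of transpose."""
        for seed in range(3):
            u = _random_image(tiny_spec, seed)
            w = _random_sinogram(tiny_spec, 100 + seed)
            lhs = np.sum(xr.forward_apply(u, tiny_spec).values * w.values)
            rhs = np.sum(u.values * xr.adjoint_apply(w, tiny_spec).values)
            denom = np.linalg.norm(u.values) * np.linalg.norm(w.values)
            assert abs(lhs - rhs) <= 1e-10 * denom

    def test_matrix_free_matches_dense_oracle(self, tiny_spec):
        mat = assemble_dense(tiny_spec)
        u = _random_image(tiny_spec, 5)
        w = _random_sinogram(tiny_spec, 6)
        fwd = xr.forward_apply(u, tiny_spec).values.ravel()
        np.testing.assert_allclose(
            mat @ u.values.ravel(), fwd, rtol=1e-10, atol=1e-10 * np.abs(fwd).max()
        )
        adj = xr.adjoint_apply(w, tiny_spec).values.ravel()
        np.testing.assert_allclose(
            mat.T @ w.values.ravel(), adj, rtol=1e-10, atol=1e-10 * np.abs(adj).max()
        )

    def test_dense_guard_rejects_large_instances(self):
        grid = xr.make_grid(2e-2, 1e-4)
        ring = xr.make_ring(5e-2, 64, 360.0)
        ta = xr.make_time_axis(grid, ring, 20e6)
        spec = OperatorSpec(grid, ring, ta, n_quadrature=100)
        with pytest.raises(ValueError):
            assemble_dense(spec)

    def test_unreachable_pixel_gives_zero_column(self):
        """A pixel whose distance band misses the time window projects to zero."""
        grid = xr.make_grid(8e-3, 1e-3)
        ring = xr.make_ring(5e-2, 4, 360.0)
        # window far too late: starts after every pixel's farthest arrival
        ta = xr.TimeAxis(t0=45e-6, dt=5e-7, n_samples=8)
        spec = OperatorSpec(grid, ring, ta, n_quadrature=30)
        mat = assemble_dense(spec)
        assert np.allclose(mat, 0.0)

    def test_rotation_equivariance_at_90_degrees(self):
        """Rotating image and detectors together leaves the sinogram unchanged."""
        grid = xr.make_grid(8e-3, 2e-4)
        rng = np.random.default_rng(0)
        base = rng.standard_normal(grid.shape)
        ring0 = xr.make_ring(3e-2, 4, 360.0, start_angle_deg=0.0)
        ring90 = xr.make_ring(3e-2, 4, 360.0, start_angle_deg=90.0)
        ta = xr.make_time_axis(grid, ring0, 5e6)
        s0 = xr.forward_apply(
            xr.SourceImage(base, grid), OperatorSpec(grid, ring0, ta, 200)
        )
        # +90 deg CCW rotation of f(x,y) on the symmetric pixel-centred grid:
        # f'(x_i, y_j) = f(y_j, -x_i)  ->  rot[j, i] = base[n-1-i, j]
        rot = base.T[:, ::-1]
        s90 = xr.forward_apply(
            xr.SourceImage(rot, grid), OperatorSpec(grid, ring90, ta, 200)
        )
        np.testing.assert_allclose(s90.values, s0.values, rtol=1e-8, atol=1e-8)
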