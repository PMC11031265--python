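"""Weighting, back-projection, MBP and LSQR inversion behaviour."""

from dataclasses import replace

import numpy as np
import pytest

import xactring as xr
from xactring.corruption import add_channel_offset
from xactring.phantoms import disc, make_shape_phantom
from xactring.reconstruct import (
    ReconConfig,
    WeightSpec,
    crop_sinogram,
    detector_mean_removal,
    laplacian_apply,
    pad_sinogram,
    reconstruct_bp,
    reconstruct_lsqr,
    reconstruct_mbp,
)


def _random_sinogram(spec, seed=0):
    rng = np.random.default_rng(seed)
    shape = (spec.ring.n_detectors, spec.time_axis.n_samples)
    return xr.Sinogram(rng.standard_normal(shape), spec.ring, spec.time_axis)


class TestDetectorMeanRemoval:
    def test_constant_columns_annihilated(self, tiny_spec):
        """S 1 = 0: a per-time-step constant across detectors maps to zero."""
        rng = np.random.default_rng(0)
        nd, nt = tiny_spec.ring.n_detectors, tiny_spec.time_axis.n_samples
        c = rng.standard_normal(nt)
        sino = xr.Sinogram(np.tile(c, (nd, 1)), tiny_spec.ring, tiny_spec.time_axis)
        out = detector_mean_removal(sino, WeightSpec(corrected=True))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_idempotent_in_limit_mode(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 1)
        w = WeightSpec(corrected=True, mode="limit")
        once = detector_mean_removal(sino, w)
        twice = detector_mean_removal(once, w)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-13,
                                   atol=1e-15)

    def test_full_mode_approaches_scaled_identity_for_tiny_beta(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 2)
        sigma, ratio = 2.0, 1e-6
        w = WeightSpec(corrected=True, mode="full", sigma=sigma,
                       beta=ratio * sigma)
        out = detector_mean_removal(sino, w)
        target = sino.values / sigma**2
        rel = np.linalg.norm(out.values - target) / np.linalg.norm(target)
        assert rel <= ratio**2 * sino.n_detectors

    def test_full_mode_requires_sigma_and_beta(self):
        with pytest.raises(ValueError):
            WeightSpec(corrected=True, mode="full")


class TestLaplacian:
    def _image(self, values):
        grid = xr.make_grid(len(values) * 1e-3, 1e-3)
        return xr.SourceImage(values, grid)

    def test_constant_image_zero_in_interior(self):
        img = self._image(np.full((6, 6), 2.0))
        out = laplacian_apply(img)
        np.testing.assert_allclose(out.values[1:-1, 1:-1], 0.0, atol=1e-14)

    def test_unit_pixel_stencil(self):
        v = np.zeros((5, 5))
        v[2, 2] = 1.0
        out = laplacian_apply(self._image(v)).values
        assert out[2, 2] == 4.0
        assert out[1, 2] == out[3, 2] == out[2, 1] == out[2, 3] == -1.0
        assert np.count_nonzero(out) == 5

    def test_self_adjointness(self):
        rng = np.random.default_rng(3)
        u = self._image(rng.standard_normal((7, 7)))
        w = self._image(rng.standard_normal((7, 7)))
        lhs = np.sum(laplacian_apply(u).values * w.values)
        rhs = np.sum(u.values * laplacian_apply(w).values)
        assert abs(lhs - rhs) <= 1e-12 * abs(lhs)


class TestBackProjection:
    def test_zero_sinogram_gives_zero_image(self, tiny_spec):
        sino = xr.Sinogram(
            np.zeros((tiny_spec.ring.n_detectors, tiny_spec.time_axis.n_samples)),
            tiny_spec.ring, tiny_spec.time_axis,
        )
        out = reconstruct_bp(sino, tiny_spec)
        assert np.all(out.values == 0.0)

    def test_linearity(self, tiny_spec):
        s1, s2 = _random_sinogram(tiny_spec, 4), _random_sinogram(tiny_spec, 5)
        combo = s1.with_values(2.0 * s1.values - 0.5 * s2.values)
        lhs = reconstruct_bp(combo, tiny_spec).values
        rhs = (2.0 * reconstruct_bp(s1, tiny_spec).values
               - 0.5 * reconstruct_bp(s2, tiny_spec).values)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-11, atol=1e-12)

    def test_disc_phantom_peak_lands_inside_disc(self):
        a = 3e-3
        sc = xr.build_scenario(
            seed=1, snr_db=np.inf, offset_ratio=0.0,
            phantom=lambda g: make_shape_phantom(g, [(disc(0, 0, a), 1.0)]),
            extent=2e-2, forward_spacing=2.5e-4, recon_spacing=5e-4,
            n_detectors=32, fs=4e6, nq_forward=200, nq_recon=120,
        )
        bp = reconstruct_bp(sc.clean, sc.recon_spec)
        iy, ix = np.unravel_index(np.argmax(bp.values), bp.values.shape)
        g = sc.recon_spec.grid
        assert np.hypot(g.x_centers[ix], g.y_centers[iy]) < a


class TestMbp:
    def _cfg(self, spec, corrected=True):
        return ReconConfig(operator_spec=spec, algorithm="MBP",
                           weight=WeightSpec(corrected=corrected))

    def test_corrected_mbp_invariant_to_offsets(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 6)
        corrupted = add_channel_offset(sino, 5.0, seed=7)
        cfg = self._cfg(tiny_spec)
        a = reconstruct_mbp(sino, cfg).values
        b = reconstruct_mbp(corrupted, cfg).values
        assert np.linalg.norm(a - b) <= 1e-10 * np.linalg.norm(a)

    def test_pure_offset_data(self, tiny_spec):
        """Uncorrected MBP of pure offsets rings; corrected is exactly zero."""
        nd, nt = tiny_spec.ring.n_detectors, tiny_spec.time_axis.n_samples
        rng = np.random.default_rng(8)
        z = rng.standard_normal(nt)
        pure = xr.Sinogram(np.tile(z, (nd, 1)), tiny_spec.ring,
                           tiny_spec.time_axis)
        corrected = reconstruct_mbp(pure, self._cfg(tiny_spec, True))
        uncorrected = reconstruct_mbp(pure, self._cfg(tiny_spec, False))
        np.testing.assert_allclose(corrected.values, 0.0, atol=1e-12)
        assert np.linalg.norm(uncorrected.values) > 0.0

    def test_matches_dense_oracle(self, tiny_spec):
        from xactring.forward import assemble_dense

        sino = _random_sinogram(tiny_spec, 9)
        mat = assemble_dense(tiny_spec)
        weighted = detector_mean_removal(sino, WeightSpec(corrected=True))
        expected = (mat.T @ weighted.values.ravel()).reshape(tiny_spec.grid.shape)
        got = reconstruct_mbp(sino, self._cfg(tiny_spec)).values
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)


class TestLsqr:
    def _cfg(self, spec, **kw):
        base = dict(operator_spec=spec, algorithm="LSQR",
                    weight=WeightSpec(corrected=True), max_iters=15)
        base.update(kw)
        return ReconConfig(**base)

    def test_corrected_solution_invariant_to_offsets(self, tiny_spec):
        """S wipes the offsets from the data, so the normal equations match.

        A little regularization keeps the tiny instance well conditioned so
        the identical weighted systems stay identical through the iteration
        (unregularized, the near-null space amplifies round-off).
        """
        sino = _random_sinogram(tiny_spec, 10)
        corrupted = add_channel_offset(sino, 4.0, seed=11)
        cfg = self._cfg(tiny_spec, reg_weight=1.0)
        a, _ = reconstruct_lsqr(sino, cfg)
        b, _ = reconstruct_lsqr(corrupted, cfg)
        rel = np.linalg.norm(a.values - b.values) / np.linalg.norm(a.values)
        assert rel <= 1e-8

    def test_noiseless_smooth_phantom_inverts_accurately(self):
        """Full-view noiseless data from a smooth source: rho >= 0.98."""

        def blobs(g):
            x, y = g.meshgrid()
            v = (np.exp(-((x - 1e-3) ** 2 + (y + 1e-3) ** 2) / (2 * 2.5e-3**2))
                 + 0.6 * np.exp(-((x + 3e-3) ** 2 + (y - 2e-3) ** 2)
                                / (2 * 1.5e-3**2)))
            return xr.SourceImage(v, g)

        sc = xr.build_scenario(
            seed=1, snr_db=np.inf, offset_ratio=0.0, phantom=blobs,
            extent=2e-2, forward_spacing=2.5e-4, recon_spacing=5e-4,
            n_detectors=32, fs=4e6, nq_forward=200, nq_recon=120,
        )
        cfg = self._cfg(sc.recon_spec, weight=WeightSpec(corrected=False),
                        max_iters=50)
        img, log = reconstruct_lsqr(sc.clean, cfg)
        assert xr.pearson_rho(img, sc.truth_recon) >= 0.98

    def test_residual_monotone_over_iterations(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 12)
        cfg = self._cfg(tiny_spec, max_iters=10, reg_weight=0.1)
        _, log = reconstruct_lsqr(sino, cfg, history=True)
        assert np.all(np.diff(log.residual_norms) <= 1e-12)

    def test_huge_regularization_flattens_solution(self, small_scenario):
        sc = small_scenario
        lo = self._cfg(sc.recon_spec, reg_weight=1e-2, max_iters=15)
        hi = self._cfg(sc.recon_spec, reg_weight=1e4, max_iters=15)
        img_lo, _ = reconstruct_lsqr(sc.noisy, lo)
        img_hi, _ = reconstruct_lsqr(sc.noisy, hi)
        assert (np.linalg.norm(laplacian_apply(img_hi).values)
                < 0.05 * np.linalg.norm(laplacian_apply(img_lo).values))

    def test_geometry_mismatch_rejected(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 13)
        other_grid = xr.make_grid(8e-3, 2e-3)
        from xactring.forward import OperatorSpec

        other = OperatorSpec(other_grid, tiny_spec.ring, tiny_spec.time_axis, 20)
        wrong_ring = xr.make_ring(5e-2, 8, 360.0)
        bad = xr.Sinogram(
            np.zeros((8, tiny_spec.time_axis.n_samples)), wrong_ring,
            tiny_spec.time_axis,
        )
        with pytest.raises(ValueError):
            reconstruct_lsqr(bad, self._cfg(tiny_spec))


class TestPadCrop:
    def test_zero_padding_is_identity(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 14)
        assert pad_sinogram(sino, 0) is sino

    def test_pad_then_crop_roundtrip(self, tiny_spec):
        sino = _random_sinogram(tiny_spec, 15)
        padded = pad_sinogram(sino, 7)
        assert padded.time_axis.t0 == pytest.approx(
            sino.time_axis.t0 - 7 * sino.time_axis.dt
        )
        np.testing.assert_array_equal(padded.values[:, :7], 0.0)
        back = crop_sinogram(padded, 7)
        np.testing.assert_array_equal(back.values, sino.values)
        assert back.time_axis == sino.time_axis
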