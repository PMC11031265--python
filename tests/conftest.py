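"""Shared fixtures: tiny geometries, oracle phantoms, reduced scenarios."""

from __future__ import annotations

import numpy as np
import pytest

import xactring as xr
from xactring.forward import OperatorSpec


@pytest.fixture(scope="session")
def tiny_spec() -> OperatorSpec:
    """8x8 grid, 4 detectors, Nq=50 — small enough for the dense oracle."""
    grid = xr.make_grid(8e-3, 1e-3)
    ring = xr.make_ring(5e-2, 4, 360.0)
    ta = xr.make_time_axis(grid, ring, 2e6)
    return OperatorSpec(grid, ring, ta, n_quadrature=50)


@pytest.fixture(scope="session")
def small_scenario() -> xr.Scenario:
    """Reduced 2 cm scenario with 5 dB noise and 3-sigma channel offsets."""
    return xr.build_scenario(
        seed=3,
        view_deg=360.0,
        snr_db=5.0,
        offset_ratio=3.0,
        extent=2e-2,
        forward_spacing=2.5e-4,
        recon_spacing=5e-4,
        n_detectors=32,
        fs=4e6,
        nq_forward=200,
        nq_recon=120,
    )


def antialiased_disc(grid: xr.ImageGrid, radius: float, amplitude: float,
                     supersample: int = 4) -> xr.SourceImage:
    """Centered disc rasterized with sub-pixel coverage (smooth edge)."""
    x, y = grid.meshgrid()
    h = grid.spacing
    cov = np.zeros(grid.shape)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    for dx in offs:
        for dy in offs:
            cov += ((x + dx * h) ** 2 + (y + dy * h) ** 2) <= radius**2
    return xr.SourceImage(amplitude * cov / supersample**2, grid)


def disc_arc_integral_closed_form(
    amplitude: float, disc_radius: float, detector_distance: float, vt: np.ndarray
) -> np.ndarray:
    """Analytic dtheta arc integral of a centered disc seen from distance R.

    For |R - a| < vt < R + a the arc of radius vt about the detector cuts
    the disc over the angle 2*arccos((R^2 + (vt)^2 - a^2) / (2 R vt));
    outside that band the integral is zero.
    """
    R, a = detector_distance, disc_radius
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (R**2 + vt**2 - a**2) / (2.0 * R * vt)
    inside = (vt > abs(R - a)) & (vt < R + a) & (np.abs(c) <= 1.0)
    out = np.zeros_like(vt, dtype=float)
    out[inside] = amplitude * 2.0 * np.arccos(np.clip(c[inside], -1.0, 1.0))
    return out
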