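"""Synthetic initial-pressure phantoms and seeded end-to-end scenarios.

Phantoms are defined analytically (shape primitives with amplitudes, or a
thin-line resolution target) and rasterized onto any grid, so the same
truth can be sampled on a fine grid for data generation and on a coarser
grid for reconstruction.  Scenario building deliberately uses *different*
forward and reconstruction discretisations (grid spacing and quadrature)
to avoid the inverse crime of inverting the exact data-generating
operator.

Default scenario conditions: 2 cm square region of interest inside a
5 cm-radius ring of 128 detectors, 20 MHz sampling, forward model at
30 um / ~1000 quadrature nodes, reconstruction at 60 um / ~600 nodes,
5 dB SNR additive noise, channel offsets at 3x the noise std.  Reduced
sizes can be passed explicitly for quick studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .corruption import DEFAULT_OFFSET_RATIO, add_awgn, add_channel_offset
from .forward import OperatorSpec, Sinogram, SourceImage, forward_apply
from .geometry import (
    DetectorRing,
    ImageGrid,
    make_grid,
    make_ring,
    make_time_axis,
    ring_subset,
)

__all__ = [
    "LinePhantomSpec",
    "make_line_phantom",
    "make_shape_phantom",
    "disc",
    "rectangle",
    "annulus",
    "open_annulus",
    "default_shape_phantom",
    "Scenario",
    "build_scenario",
]

MaskGenerator = Callable[[ImageGrid], np.ndarray]


@dataclass(frozen=True)
class LinePhantomSpec:
    """Thin parallel vertical lines on a uniform background.

    Contrasts are amplitude ratios line/background (>= 1); the default
    four lines span contrasts 1.2-1.9 evenly with 100 um width and 2 mm
    centre-to-centre spacing.
    """

    line_width: float = 100e-6
    contrasts: tuple[float, ...] = (1.2, 1.2 + 0.7 / 3, 1.2 + 1.4 / 3, 1.9)
    background_level: float = 1.0
    x_centers: tuple[float, ...] | None = None  # None -> 2 mm pitch, centred
    line_length: float | None = None  # None -> 60% of grid height

    def __post_init__(self) -> None:
        if self.line_width <= 0:
            raise ValueError("line_width must be positive")
        if any(c < 1 for c in self.contrasts):
            raise ValueError("contrasts must be >= 1 (ratios vs background)")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if self.x_centers is not None and len(self.x_centers) != len(self.contrasts):
            raise ValueError("x_centers and contrasts must have equal length")

    def resolved_centers(self, grid: ImageGrid) -> np.ndarray:
        if self.x_centers is not None:
            return np.asarray(self.x_centers, dtype=float)
        n = len(self.contrasts)
        pitch = 2e-3
        return (np.arange(n) - (n - 1) / 2.0) * pitch

    def resolved_length(self, grid: ImageGrid) -> float:
        return self.line_length if self.line_length is not None else 0.6 * grid.extent_y


def _interval_overlap_fractions(
    centers: np.ndarray, h: float, lo: float, hi: float
) -> np.ndarray:
    """Fraction of each pixel interval [c-h/2, c+h/2] covered by [lo, hi]."""
    left = np.maximum(centers - h / 2.0, lo)
    right = np.minimum(centers + h / 2.0, hi)
    return np.clip(right - left, 0.0, None) / h


def make_line_phantom(grid: ImageGrid, spec: LinePhantomSpec) -> SourceImage:
    """Rasterize the line phantom with area-weighted (sub-pixel) coverage.

    Each line is a rectangle of the given width; a pixel's value is the
    background plus the covered-area fraction times the line excess, so
    lines thinner than a pixel are represented with conserved mass.
    """
    xc = spec.resolved_centers(grid)
    length = spec.resolved_length(grid)
    half_w = spec.line_width / 2.0
    half_l = length / 2.0
    if np.any(np.abs(xc) + half_w > grid.extent_x / 2.0) or half_l > grid.extent_y / 2.0:
        raise ValueError("line phantom does not fit inside the grid")
    img = np.full(grid.shape, spec.background_level, dtype=float)
    fy = _interval_overlap_fractions(grid.y_centers, grid.spacing, -half_l, half_l)
    for x0, contrast in zip(xc, spec.contrasts):
        fx = _interval_overlap_fractions(
            grid.x_centers, grid.spacing, x0 - half_w, x0 + half_w
        )
        img += np.outer(fy, fx) * (contrast - 1.0) * spec.background_level
    return SourceImage(img, grid)


def disc(cx: float, cy: float, radius: float) -> MaskGenerator:
    """Binary disc mask generator (evaluated at pixel centres)."""

    def gen(grid: ImageGrid) -> np.ndarray:
        x, y = grid.meshgrid()
        return ((x - cx) ** 2 + (y - cy) ** 2 <= radius**2).astype(float)

    return gen


def rectangle(cx: float, cy: float, width: float, height: float) -> MaskGenerator:
    """Axis-aligned binary rectangle mask generator."""

    def gen(grid: ImageGrid) -> np.ndarray:
        x, y = grid.meshgrid()
        return (
            (np.abs(x - cx) <= width / 2.0) & (np.abs(y - cy) <= height / 2.0)
        ).astype(float)

    return gen


def annulus(cx: float, cy: float, r_inner: float, r_outer: float) -> MaskGenerator:
    """Binary annulus (ring) mask generator."""

    def gen(grid: ImageGrid) -> np.ndarray:
        x, y = grid.meshgrid()
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        return ((r2 >= r_inner**2) & (r2 <= r_outer**2)).astype(float)

    return gen


def make_shape_phantom(
    grid: ImageGrid, shapes: Sequence[tuple[MaskGenerator, float]]
) -> SourceImage:
    """Sum of rasterized shapes at given amplitudes (overlaps add)."""
    if not shapes:
        raise ValueError("need at least one shape")
    img = np.zeros(grid.shape, dtype=float)
    for gen, amplitude in shapes:
        img += amplitude * gen(grid)
    return SourceImage(img, grid)


def open_annulus(
    cx: float, cy: float, r_inner: float, r_outer: float
) -> MaskGenerator:
    """U-shaped open ring: annulus restricted to y <= cy + r_inner."""

    def gen(grid: ImageGrid) -> np.ndarray:
        x, y = grid.meshgrid()
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        return (
            (r2 >= r_inner**2) & (r2 <= r_outer**2) & (y <= cy + r_inner)
        ).astype(float)

    return gen


def default_shape_phantom_shapes(extent: float = 2e-2) -> list[tuple[MaskGenerator, float]]:
    """Letter-like multi-contrast shape set scaled to a square ROI.

    A vertical bar, a disc, and an open low-contrast "U"-like ring
    emulate a multi-target source in which one structure has distinctly
    lower contrast than the rest, so that ring artifacts can visibly
    eclipse it.
    """
    s = extent / 2e-2  # scale factor relative to the 2 cm reference ROI
    return [
        (rectangle(-5e-3 * s, 1.5e-3 * s, 1.6e-3 * s, 9e-3 * s), 1.0),
        (disc(4.5e-3 * s, 2.5e-3 * s, 2.4e-3 * s), 0.8),
        (open_annulus(0.0, -3.5e-3 * s, 1.6e-3 * s, 3.0e-3 * s), 0.3),
    ]


def default_shape_phantom(grid: ImageGrid) -> SourceImage:
    """Rasterize the default letter-like phantom on *grid*."""
    return make_shape_phantom(grid, default_shape_phantom_shapes(grid.extent_x))


@dataclass(frozen=True)
class Scenario:
    """One seeded synthetic acquisition: truth plus clean/noisy/corrupted data."""

    truth_fine: SourceImage
    truth_recon: SourceImage
    clean: Sinogram
    noisy: Sinogram
    corrupted: Sinogram
    forward_spec: OperatorSpec
    recon_spec: OperatorSpec
    noise_sigma: float
    offset_std: float
    manifest: dict


def build_scenario(
    seed: int = 0,
    view_deg: float = 360.0,
    snr_db: float = 5.0,
    offset_ratio: float = DEFAULT_OFFSET_RATIO,
    phantom: Callable[[ImageGrid], SourceImage] | None = None,
    extent: float = 2e-2,
    forward_spacing: float = 30e-6,
    recon_spacing: float = 60e-6,
    radius: float = 5e-2,
    n_detectors: int = 128,
    fs: float = 20e6,
    nq_forward: int = 1000,
    nq_recon: int = 600,
) -> Scenario:
    """Simulate a full acquisition with seeded noise and channel offsets.

    The truth is rasterized on the fine grid, forward-projected with the
    fine-quadrature operator, then corrupted: AWGN at ``snr_db`` first,
    then per-time-step offsets with ``beta = offset_ratio * sigma``.
    Reconstruction consumers use ``recon_spec`` (coarse grid/quadrature)
    and ``truth_recon`` for evaluation.  Same seed, same scenario,
    bit-for-bit.
    """
    if phantom is None:
        phantom = default_shape_phantom
    fine = make_grid(extent, forward_spacing)
    coarse = make_grid(extent, recon_spacing)
    full_ring = make_ring(radius, n_detectors, 360.0)
    ring = ring_subset(full_ring, view_deg) if view_deg < 360 else full_ring
    ta = make_time_axis(fine, ring, fs)
    forward_spec = OperatorSpec(fine, ring, ta, n_quadrature=nq_forward)
    recon_spec = OperatorSpec(coarse, ring, ta, n_quadrature=nq_recon)

    truth_fine = phantom(fine)
    truth_recon = phantom(coarse)
    clean = forward_apply(truth_fine, forward_spec)

    from .corruption import NoiseSpec

    nspec = NoiseSpec(snr_db=snr_db, seed=seed)
    noisy, sigma = add_awgn(clean, snr_db, nspec.noise_seed)
    beta = offset_ratio * sigma
    corrupted = (
        add_channel_offset(noisy, beta, nspec.offset_seed)
        if beta > 0
        else noisy.with_values(noisy.values.copy(), tag="corrupted")
    )

    manifest = {
        "package_version": _pkg_version,
        "seed": int(seed),
        "noise_seed": int(nspec.noise_seed),
        "offset_seed": int(nspec.offset_seed),
        "view_deg": float(view_deg),
        "snr_db": float(snr_db),
        "offset_ratio": float(offset_ratio),
        "noise_sigma": float(sigma),
        "offset_std": float(beta),
        "extent_m": float(extent),
        "forward_spacing_m": float(forward_spacing),
        "recon_spacing_m": float(recon_spacing),
        "ring_radius_m": float(radius),
        "n_detectors_full": int(n_detectors),
        "n_detectors_active": int(ring.n_detectors),
        "sound_speed_m_s": float(ring.sound_speed),
        "sampling_freq_hz": float(fs),
        "nq_forward": int(nq_forward),
        "nq_recon": int(nq_recon),
        "t0_s": float(ta.t0),
        "n_samples": int(ta.n_samples),
    }
    return Scenario(
        truth_fine=truth_fine,
        truth_recon=truth_recon,
        clean=clean,
        noisy=noisy,
        corrupted=corrupted,
        forward_spec=forward_spec,
        recon_spec=recon_spec,
        noise_sigma=sigma,
        offset_std=beta,
        manifest=manifest,
    )
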