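"""Discrete XACT measurement operator.

The acoustic pressure recorded by a point detector on the ring is, after
normalising physical prefactors to unity, the time derivative of the
integral of the initial-pressure (X-ray energy deposition) map over the
circular arc of radius ``v*t`` centred on the detector:

    p(r, t) = d/dt  \\int_{|r - r'| = v t} H(r') dtheta .

The integral is taken in the angle subtended at the detector (dtheta
measure), which absorbs the 1/(v t) geometrical factor of the spherical
mean.  Discretising H on a pixel grid and the integral with an Nq-point
midpoint rule in angle yields a linear operator M mapping the flattened
image ``h`` to the flattened sinogram ``p = M h``.  Both ``M h`` and
``M^T p`` are applied matrix-free (the quadrature weights are re-derived
on the fly per detector), and :func:`assemble_dense` provides an explicit
matrix for small instances used as a test oracle.

The time derivative uses second-order central differences in the interior
and first-order one-sided stencils at the two ends; it is part of M, and
the adjoint applies its exact transpose so that the operator pair passes
the dot test to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .geometry import DetectorRing, ImageGrid, TimeAxis

__all__ = [
    "SourceImage",
    "ArcIntegralSeries",
    "Sinogram",
    "OperatorSpec",
    "arc_integrals",
    "arc_integrals_adjoint",
    "time_derivative",
    "time_derivative_adjoint",
    "forward_apply",
    "adjoint_apply",
    "assemble_dense",
]


@dataclass(frozen=True)
class SourceImage:
    """Initial-pressure / X-ray energy-deposition map on an :class:`ImageGrid`.

    ``values`` has shape ``(ny, nx)``; the map is implicitly zero outside
    the grid.
    """

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.shape:
            raise ValueError(
                f"image shape {v.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("image values must be finite")


@dataclass(frozen=True)
class ArcIntegralSeries:
    """Arc integrals before time differentiation, shape ``(Nd, Nt)``."""

    values: np.ndarray
    ring: DetectorRing
    time_axis: TimeAxis

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        expected = (self.ring.n_detectors, self.time_axis.n_samples)
        if v.shape != expected:
            raise ValueError(f"series shape {v.shape} != {expected}")


@dataclass(frozen=True)
class Sinogram:
    """Detector x time pressure measurements with provenance flags.

    ``provenance`` accumulates processing-step tags such as ``"clean"``,
    ``"noisy"``, ``"corrupted"``, ``"filtered"``, ``"weighted"``.
    """

    values: np.ndarray
    ring: DetectorRing
    time_axis: TimeAxis
    provenance: tuple[str, ...] = ("clean",)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        expected = (self.ring.n_detectors, self.time_axis.n_samples)
        if v.shape != expected:
            raise ValueError(f"sinogram shape {v.shape} != {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram values must be finite")
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def with_values(self, values: np.ndarray, tag: str | None = None) -> "Sinogram":
        prov = self.provenance + (tag,) if tag else self.provenance
        return Sinogram(values, self.ring, self.time_axis, prov)

    @property
    def n_detectors(self) -> int:
        return self.ring.n_detectors

    @property
    def n_samples(self) -> int:
        return self.time_axis.n_samples


@dataclass(frozen=True)
class OperatorSpec:
    """Geometry + quadrature defining one forward/adjoint operator pair.

    ``n_quadrature`` is the number of angular quadrature nodes per arc
    (about 1000 for data generation, about 600 for reconstruction by
    default; always use the same spec for a forward/adjoint pair).
    """

    grid: ImageGrid
    ring: DetectorRing
    time_axis: TimeAxis
    n_quadrature: int = 600

    def __post_init__(self) -> None:
        if self.n_quadrature < 2:
            raise ValueError("need at least 2 quadrature nodes per arc")
        self.ring.validate_grid(self.grid)

    @property
    def n_data(self) -> int:
        return self.ring.n_detectors * self.time_axis.n_samples


def _detector_sectors(spec: OperatorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Angular sector (phi_min, width) subtending the grid bounding box.

    Seen from a detector outside the box, the box subtends a contiguous
    angular interval whose extremes are attained at corners.  Angles are
    measured about the detector; quadrature nodes are restricted to this
    sector so none are wasted on empty arc segments.
    """
    pos = spec.ring.positions  # (Nd, 2)
    hx = spec.grid.extent_x / 2.0
    hy = spec.grid.extent_y / 2.0
    corners = np.array([[hx, hy], [hx, -hy], [-hx, hy], [-hx, -hy]])  # (4, 2)
    # angle of each corner as seen from each detector, relative to the
    # direction toward the box centre (origin) to avoid branch-cut wrap
    ref = np.arctan2(-pos[:, 1], -pos[:, 0])  # (Nd,)
    d = corners[None, :, :] - pos[:, None, :]  # (Nd, 4, 2)
    ang = np.arctan2(d[:, :, 1], d[:, :, 0])  # (Nd, 4)
    rel = (ang - ref[:, None] + np.pi) % (2 * np.pi) - np.pi
    phi_min = ref + rel.min(axis=1)
    width = rel.max(axis=1) - rel.min(axis=1)
    return phi_min, width


def _bilinear_gather(
    img: np.ndarray, grid: ImageGrid, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Sample *img* bilinearly at points (x, y); zero outside the grid."""
    h = grid.spacing
    gx = x / h + (grid.nx - 1) / 2.0
    gy = y / h + (grid.ny - 1) / 2.0
    i0 = np.floor(gx).astype(np.int64)
    j0 = np.floor(gy).astype(np.int64)
    fx = gx - i0
    fy = gy - j0
    out = np.zeros(np.broadcast(x, y).shape, dtype=float)
    for di, dj, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        ii = i0 + di
        jj = j0 + dj
        valid = (ii >= 0) & (ii < grid.nx) & (jj >= 0) & (jj < grid.ny)
        if np.any(valid):
            out[valid] += w[valid] * img[jj[valid], ii[valid]]
    return out


def _bilinear_scatter(
    acc: np.ndarray, grid: ImageGrid, x: np.ndarray, y: np.ndarray, val: np.ndarray
) -> None:
    """Transpose of :func:`_bilinear_gather`: accumulate *val* into *acc*."""
    h = grid.spacing
    gx = x / h + (grid.nx - 1) / 2.0
    gy = y / h + (grid.ny - 1) / 2.0
    i0 = np.floor(gx).astype(np.int64)
    j0 = np.floor(gy).astype(np.int64)
    fx = gx - i0
    fy = gy - j0
    n = grid.nx * grid.ny
    flat = acc.reshape(-1)
    for di, dj, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        ii = i0 + di
        jj = j0 + dj
        valid = (ii >= 0) & (ii < grid.nx) & (jj >= 0) & (jj < grid.ny)
        if np.any(valid):
            idx = jj[valid] * grid.nx + ii[valid]
            flat += np.bincount(idx, weights=(w * val)[valid], minlength=n)


def arc_integrals(image: SourceImage, spec: OperatorSpec) -> ArcIntegralSeries:
    """Integrate the image over arcs of radius ``v*t`` about each detector.

    Entry ``(d, q)`` is the dtheta-measure integral of the bilinearly
    interpolated image over the arc of radius ``v * t(q)`` centred on
    detector ``d``, clipped to the angular sector subtending the grid
    bounding box: the mean of ``Nq`` midpoint samples times the subtended
    angle.  Linear in the image; zero where the arc misses the grid.
    """
    if image.grid != spec.grid:
        raise ValueError("image grid does not match operator spec grid")
    ring, ta = spec.ring, spec.time_axis
    v = ring.sound_speed
    radii = v * ta.times  # (Nt,)
    phi_min, width = _detector_sectors(spec)
    nq = spec.n_quadrature
    frac = (np.arange(nq) + 0.5) / nq
    out = np.empty((ring.n_detectors, ta.n_samples), dtype=float)
    img = image.values
    pos = ring.positions
    active = radii > 0
    for d in range(ring.n_detectors):
        phi = phi_min[d] + width[d] * frac  # (Nq,)
        cx, sx = np.cos(phi), np.sin(phi)
        x = pos[d, 0] + radii[active, None] * cx[None, :]
        y = pos[d, 1] + radii[active, None] * sx[None, :]
        samples = _bilinear_gather(img, spec.grid, x, y)
        out[d, active] = samples.mean(axis=1) * width[d]
        out[d, ~active] = 0.0
    return ArcIntegralSeries(out, ring, ta)


def arc_integrals_adjoint(series: ArcIntegralSeries, spec: OperatorSpec) -> SourceImage:
    """Exact transpose of :func:`arc_integrals`."""
    ring, ta = spec.ring, spec.time_axis
    if series.ring != ring or series.time_axis != ta:
        raise ValueError("series geometry does not match operator spec")
    v = ring.sound_speed
    radii = v * ta.times
    phi_min, width = _detector_sectors(spec)
    nq = spec.n_quadrature
    frac = (np.arange(nq) + 0.5) / nq
    acc = np.zeros(spec.grid.shape, dtype=float)
    pos = ring.positions
    active = radii > 0
    for d in range(ring.n_detectors):
        phi = phi_min[d] + width[d] * frac
        cx, sx = np.cos(phi), np.sin(phi)
        x = pos[d, 0] + radii[active, None] * cx[None, :]
        y = pos[d, 1] + radii[active, None] * sx[None, :]
        # each node carries weight (series value) * width / Nq
        val = np.broadcast_to(
            (series.values[d, active] * width[d] / nq)[:, None], x.shape
        )
        _bilinear_scatter(acc, spec.grid, x, y, np.ascontiguousarray(val))
    return SourceImage(acc, spec.grid)


def _derivative_matrix(time_axis: TimeAxis) -> sp.csr_matrix:
    """Sparse d/dt stencil: central interior, first-order one-sided ends."""
    nt = time_axis.n_samples
    dt = time_axis.dt
    rows, cols, vals = [], [], []
    rows += [0, 0]
    cols += [0, 1]
    vals += [-1.0 / dt, 1.0 / dt]
    q = np.arange(1, nt - 1)
    rows += list(q) + list(q)
    cols += list(q - 1) + list(q + 1)
    vals += [-0.5 / dt] * (nt - 2) + [0.5 / dt] * (nt - 2)
    rows += [nt - 1, nt - 1]
    cols += [nt - 2, nt - 1]
    vals += [-1.0 / dt, 1.0 / dt]
    return sp.csr_matrix((vals, (rows, cols)), shape=(nt, nt))


def time_derivative(series: ArcIntegralSeries) -> Sinogram:
    """Differentiate arc integrals along time to obtain the pressure sinogram."""
    if series.time_axis.n_samples < 3:
        raise ValueError("need at least 3 time samples to differentiate")
    d_mat = _derivative_matrix(series.time_axis)
    vals = series.values @ d_mat.T
    return Sinogram(vals, series.ring, series.time_axis, provenance=("clean",))


def time_derivative_adjoint(sino: Sinogram) -> ArcIntegralSeries:
    """Exact transpose of :func:`time_derivative` (not an anti-derivative)."""
    d_mat = _derivative_matrix(sino.time_axis)
    # forward is values @ D.T, so the adjoint is values @ D
    vals = (d_mat.T @ sino.values.T).T
    return ArcIntegralSeries(np.ascontiguousarray(vals), sino.ring, sino.time_axis)


def forward_apply(image: SourceImage, spec: OperatorSpec) -> Sinogram:
    """Matrix-free matvec ``M h``: arc integrals followed by d/dt."""
    return time_derivative(arc_integrals(image, spec))


def adjoint_apply(sino: Sinogram, spec: OperatorSpec) -> SourceImage:
    """Matrix-free ``M^T p``: transpose-derivative then arc-integral scatter."""
    if sino.ring != spec.ring or sino.time_axis != spec.time_axis:
        raise ValueError("sinogram geometry does not match operator spec")
    return arc_integrals_adjoint(time_derivative_adjoint(sino), spec)


#: safety limit on explicitly assembled operator size
_DENSE_GUARD = 10_000_000


def assemble_dense(spec: OperatorSpec) -> np.ndarray:
    """Explicit ``(Nd*Nt, N)`` matrix of the forward operator (test oracle).

    Column ``j`` is the flattened sinogram of the ``j``-th unit-pixel image.
    Guarded to small instances; the matrix-free paths are the production
    route.
    """
    n = spec.grid.n_pixels
    m = spec.n_data
    if n * m > _DENSE_GUARD:
        raise ValueError(
            f"dense operator would have {n * m} entries (> {_DENSE_GUARD})"
        )
    mat = np.empty((m, n), dtype=float)
    for j in range(n):
        unit = np.zeros(n)
        unit[j] = 1.0
        img = SourceImage(unit.reshape(spec.grid.shape), spec.grid)
        mat[:, j] = forward_apply(img, spec).values.reshape(-1)
    return mat
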