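"""Grid, ring-array and time-axis definitions shared by all other modules.

Conventions (used everywhere in the package):

* Continuous 2D Cartesian coordinates, origin at the ring centre, x to the
  right, y up.  Detector 0 sits at ``start_angle_deg`` on the positive
  x-axis by default; detectors are ordered counter-clockwise.
* The image grid is pixel-centred and symmetric about the origin.  Image
  arrays are row-major ``(ny, nx)`` with the row index increasing in +y.
* The acoustic medium is homogeneous with a single sound speed ``v``
  (water, 1500 m/s, by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "DetectorRing",
    "TimeAxis",
    "make_grid",
    "make_ring",
    "make_time_axis",
    "ring_subset",
    "SOUND_SPEED_WATER",
]

#: Default sound speed (m/s) of the water coupling bath.
SOUND_SPEED_WATER = 1500.0


@dataclass(frozen=True)
class ImageGrid:
    """A regular, pixel-centred 2D grid symmetric about the origin.

    Parameters
    ----------
    spacing:
        Pixel pitch ``h`` in metres.
    nx, ny:
        Number of pixels along x and y.
    """

    spacing: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must have at least 2 pixels per axis")

    @property
    def extent_x(self) -> float:
        """Physical width covered by the pixels (m)."""
        return self.nx * self.spacing

    @property
    def extent_y(self) -> float:
        return self.ny * self.spacing

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of images on this grid."""
        return (self.ny, self.nx)

    @property
    def half_diagonal(self) -> float:
        """Distance from the origin to the farthest corner of the bounding box."""
        return math.hypot(self.extent_x, self.extent_y) / 2.0

    @property
    def x_centers(self) -> np.ndarray:
        """Pixel-centre x coordinates, ascending (m)."""
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.spacing

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.spacing

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Y)`` pixel-centre coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x_centers, self.y_centers)


@dataclass(frozen=True)
class DetectorRing:
    """Point detectors uniformly spaced on a circular arc.

    For a full 360 degree view the ``n_detectors`` points are spaced by
    ``coverage/n``; for a partial arc the endpoints are included and the
    spacing is ``coverage/(n - 1)``.
    """

    radius: float
    n_detectors: int
    coverage_deg: float = 360.0
    start_angle_deg: float = 0.0
    sound_speed: float = SOUND_SPEED_WATER

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.n_detectors < 2:
            raise ValueError("need at least 2 detectors")
        if not (0 < self.coverage_deg <= 360):
            raise ValueError(
                f"coverage_deg must lie in (0, 360], got {self.coverage_deg}"
            )
        if not (self.sound_speed > 0):
            raise ValueError("sound speed must be positive")

    @property
    def is_full_view(self) -> bool:
        return math.isclose(self.coverage_deg, 360.0)

    @property
    def angles_deg(self) -> np.ndarray:
        """Detector angles in degrees, counter-clockwise from +x."""
        k = np.arange(self.n_detectors)
        if self.is_full_view:
            step = self.coverage_deg / self.n_detectors
        else:
            step = self.coverage_deg / (self.n_detectors - 1)
        return self.start_angle_deg + k * step

    @property
    def positions(self) -> np.ndarray:
        """Detector positions, shape ``(n_detectors, 2)`` in metres."""
        th = np.deg2rad(self.angles_deg)
        return self.radius * np.stack([np.cos(th), np.sin(th)], axis=1)

    def validate_grid(self, grid: ImageGrid) -> None:
        """Raise if any pixel centre of *grid* is not strictly inside the ring."""
        # farthest pixel centre from the origin is a corner centre
        rmax = math.hypot(
            (grid.nx - 1) / 2.0 * grid.spacing, (grid.ny - 1) / 2.0 * grid.spacing
        )
        if rmax >= self.radius:
            raise ValueError(
                f"grid pixel centres reach {rmax:.4g} m from the centre, "
                f"outside the detection ring of radius {self.radius:.4g} m"
            )


@dataclass(frozen=True)
class TimeAxis:
    """Uniformly sampled acquisition time window ``t(q) = t0 + q*dt``."""

    t0: float
    dt: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if self.n_samples < 3:
            raise ValueError("need at least 3 time samples")

    @property
    def fs(self) -> float:
        """Sampling frequency (Hz)."""
        return 1.0 / self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt


def make_grid(extent: float, spacing: float) -> ImageGrid:
    """Square pixel-centred grid of side *extent* centred at the origin.

    ``nx = ny = round(extent / spacing)``; pixel centres sit at
    ``(j - (n-1)/2) * spacing``, symmetric about zero.
    """
    if extent <= 0 or spacing <= 0:
        raise ValueError("extent and spacing must be positive")
    n = int(round(extent / spacing))
    if n < 2:
        raise ValueError("extent/spacing must be at least 2")
    return ImageGrid(spacing=spacing, nx=n, ny=n)


def make_ring(
    radius: float,
    n_detectors: int,
    coverage_deg: float = 360.0,
    sound_speed: float = SOUND_SPEED_WATER,
    start_angle_deg: float = 0.0,
) -> DetectorRing:
    """Construct a circular detection array (full ring or contiguous arc)."""
    return DetectorRing(
        radius=radius,
        n_detectors=n_detectors,
        coverage_deg=coverage_deg,
        start_angle_deg=start_angle_deg,
        sound_speed=sound_speed,
    )


def ring_subset(
    ring: DetectorRing, coverage_deg: float, start_angle_deg: float | None = None
) -> DetectorRing:
    """Contiguous-arc subset of a full ring, keeping the original positions.

    Limited-view acquisitions reuse the detectors of the full circular array
    that fall inside the requested arc (rather than re-spreading them), so
    the angular pitch is preserved.  Returns a new :class:`DetectorRing`
    whose detectors coincide with a subset of ``ring``'s.
    """
    if not ring.is_full_view:
        raise ValueError("ring_subset expects a full-view ring")
    if not (0 < coverage_deg <= 360):
        raise ValueError("coverage_deg must lie in (0, 360]")
    if math.isclose(coverage_deg, 360.0):
        return ring
    gap = 360.0 / ring.n_detectors
    n_keep = int(math.floor(coverage_deg / gap + 1e-9)) + 1
    start = ring.start_angle_deg if start_angle_deg is None else start_angle_deg
    return DetectorRing(
        radius=ring.radius,
        n_detectors=n_keep,
        coverage_deg=(n_keep - 1) * gap,
        start_angle_deg=start,
        sound_speed=ring.sound_speed,
    )


def make_time_axis(grid: ImageGrid, ring: DetectorRing, fs: float) -> TimeAxis:
    """Time window guaranteed to cover every arc that meets the grid.

    Arcs of radius ``v*t`` centred on a detector intersect the grid bounding
    box only for ``t`` in ``[(R - rmax)/v, (R + rmax)/v]`` with ``rmax`` the
    grid half-diagonal; the returned axis covers that interval with a
    two-sample margin on each side.
    """
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    ring.validate_grid(grid)
    v = ring.sound_speed
    rmax = grid.half_diagonal
    dt = 1.0 / fs
    t_lo = max((ring.radius - rmax) / v, 0.0)
    t_hi = (ring.radius + rmax) / v
    t0 = max(t_lo - 2 * dt, 0.0)
    t_end = t_hi + 2 * dt
    n = int(math.ceil((t_end - t0) * fs)) + 1
    return TimeAxis(t0=t0, dt=dt, n_samples=n)
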