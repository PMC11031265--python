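"""Persistence for sinograms, images, run manifests and configs.

No domain-standard container exists for XACT sinograms, so the package
defines a small HDF5 schema (lossless, the production format):

* dataset ``values`` — float64 array (n_detectors x n_samples);
* attributes ``radius``, ``n_detectors``, ``coverage_deg``,
  ``start_angle_deg``, ``sound_speed``, ``t0``, ``dt``, ``n_samples``,
  ``provenance`` (list of step tags).

A CSV export (rows = detectors, columns = time samples) with a JSON
metadata sidecar is provided for inspection and interoperability; it is
lossless to the printed precision.  Images round-trip losslessly as
float TIFF with a JSON grid sidecar, and can be previewed as windowed
8-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .forward import Sinogram, SourceImage
from .geometry import DetectorRing, ImageGrid, TimeAxis

__all__ = [
    "write_sinogram",
    "read_sinogram",
    "write_sinogram_csv",
    "read_sinogram_csv",
    "write_image",
    "read_image",
    "write_image_png",
    "write_manifest",
    "read_manifest",
]

_RING_ATTRS = ("radius", "n_detectors", "coverage_deg", "start_angle_deg", "sound_speed")
_TIME_ATTRS = ("t0", "dt", "n_samples")


def _ring_meta(ring: DetectorRing) -> dict:
    return {
        "radius": ring.radius,
        "n_detectors": ring.n_detectors,
        "coverage_deg": ring.coverage_deg,
        "start_angle_deg": ring.start_angle_deg,
        "sound_speed": ring.sound_speed,
    }


def _time_meta(ta: TimeAxis) -> dict:
    return {"t0": ta.t0, "dt": ta.dt, "n_samples": ta.n_samples}


def _ring_from_meta(meta: dict) -> DetectorRing:
    return DetectorRing(
        radius=float(meta["radius"]),
        n_detectors=int(meta["n_detectors"]),
        coverage_deg=float(meta["coverage_deg"]),
        start_angle_deg=float(meta["start_angle_deg"]),
        sound_speed=float(meta["sound_speed"]),
    )


def _time_from_meta(meta: dict) -> TimeAxis:
    return TimeAxis(
        t0=float(meta["t0"]), dt=float(meta["dt"]), n_samples=int(meta["n_samples"])
    )


def write_sinogram(path: str | Path, sino: Sinogram) -> None:
    """Write a sinogram to the HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=sino.values)
        for k, v in {**_ring_meta(sino.ring), **_time_meta(sino.time_axis)}.items():
            f.attrs[k] = v
        f.attrs["provenance"] = list(sino.provenance)


def read_sinogram(path: str | Path) -> Sinogram:
    """Read a sinogram from HDF5, validating metadata and shape."""
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise ValueError(f"{path}: missing 'values' dataset")
        for attr in _RING_ATTRS + _TIME_ATTRS:
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing required attribute '{attr}'")
        values = f["values"][()]
        meta = {k: f.attrs[k] for k in _RING_ATTRS + _TIME_ATTRS}
        prov = tuple(str(p) for p in f.attrs.get("provenance", ["clean"]))
    ring = _ring_from_meta(meta)
    ta = _time_from_meta(meta)
    if values.shape != (ring.n_detectors, ta.n_samples):
        raise ValueError(
            f"{path}: values shape {values.shape} inconsistent with "
            f"n_detectors={ring.n_detectors}, n_samples={ta.n_samples}"
        )
    return Sinogram(values, ring, ta, prov)


def write_sinogram_csv(path: str | Path, sino: Sinogram) -> None:
    """CSV export (detectors x time) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, sino.values, delimiter=",", fmt="%.12e")
    sidecar = {
        "ring": _ring_meta(sino.ring),
        "time_axis": _time_meta(sino.time_axis),
        "provenance": list(sino.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_sinogram_csv(path: str | Path) -> Sinogram:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    ring = _ring_from_meta(sidecar["ring"])
    ta = _time_from_meta(sidecar["time_axis"])
    return Sinogram(values, ring, ta, tuple(sidecar.get("provenance", ("clean",))))


def write_image(path: str | Path, image: SourceImage) -> None:
    """Lossless float TIFF plus a JSON grid sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float64))
    sidecar = {
        "spacing": image.grid.spacing,
        "nx": image.grid.nx,
        "ny": image.grid.ny,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_image(path: str | Path) -> SourceImage:
    import tifffile

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = tifffile.imread(path)
    grid = ImageGrid(
        spacing=float(sidecar["spacing"]), nx=int(sidecar["nx"]), ny=int(sidecar["ny"])
    )
    if values.shape != grid.shape:
        raise ValueError(
            f"{path}: image shape {values.shape} does not match sidecar grid "
            f"{grid.shape}"
        )
    return SourceImage(values, grid)


def write_image_png(path: str | Path, image: SourceImage) -> None:
    """Windowed 8-bit preview: image min/max mapped to 0/255."""
    from PIL import Image

    v = image.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    # flip so +y (row index increasing) appears as image "up"
    arr = np.flipud((scaled * 255.0).round().astype(np.uint8))
    Image.fromarray(arr, mode="L").save(path)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
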