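"""File formats: float TIFF/CSV images, yield stacks, matrix container, YAML config.

Images are written as 32-bit float TIFF (single page for 2-D images, one
page per constant-depth slab for yield stacks) or as CSV grids, always with
a JSON sidecar recording spacing, origin and axis order.  System matrices
round-trip bit-exactly through a flat binary container: row-major 8-byte
floats next to a JSON header with the shape and assembly provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .forward import BlurryImage, ExpectedImage, ImagingSetup, YieldMap
from .optics import (
    OpticalProperties,
    PointSource,
    SlabGeometry,
    VoxelGrid,
    place_collimated_source,
)
from .sysmat import FocalPlane, SystemMatrix

__all__ = [
    "write_image",
    "read_image",
    "write_yield_map",
    "read_yield_map",
    "write_system_matrix",
    "read_system_matrix",
    "load_config",
    "setup_from_config",
    "config_hash",
]

_AXIS_ORDER_2D = ["y", "z"]
_AXIS_ORDER_3D = ["x", "y", "z"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, spacing, origin, axes) -> None:
    meta = {"spacing_cm": list(spacing), "origin_cm": list(origin), "axis_order": axes}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_image(image: np.ndarray, path, grid: VoxelGrid | None = None) -> None:
    """Write a 2-D (Ny, Nz) image as float32 TIFF or CSV, with JSON sidecar."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, image, delimiter=",")
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    if grid is not None:
        _write_sidecar(
            path, grid.spacing[1:], grid.origin[1:], _AXIS_ORDER_2D
        )


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    if path.suffix.lower() == ".csv":
        return np.atleast_2d(np.loadtxt(path, delimiter=","))
    raise ValueError(f"unsupported image format: {path.suffix!r}")


def write_yield_map(f: YieldMap, path) -> None:
    """Write a yield map as a multi-page float32 TIFF (page = constant-x slab)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(f.values, dtype=np.float32))
    _write_sidecar(path, f.grid.spacing, f.grid.origin, _AXIS_ORDER_3D)


def read_yield_map(path, grid: VoxelGrid) -> YieldMap:
    values = np.asarray(tifffile.imread(Path(path)), dtype=float)
    return YieldMap(values=values, grid=grid)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_system_matrix(r: SystemMatrix, path) -> None:
    """Serialize a system matrix: row-major float64 .bin + JSON header."""
    path = Path(path)
    np.ascontiguousarray(r.values, dtype=np.float64).tofile(path)
    header = {
        "shape": list(r.values.shape),
        "dtype": "float64",
        "order": "C",
        "dfp_cm": r.focal.depth,
        "focal_index": r.focal.index,
        "grid_counts": list(r.grid.counts),
        "grid_spacing": list(r.grid.spacing),
        "grid_origin": list(r.grid.origin),
        "provenance": r.provenance,
        "config_hash": config_hash(r.provenance),
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1))


def read_system_matrix(path) -> SystemMatrix:
    path = Path(path)
    header = json.loads(_sidecar_path(path).read_text())
    shape = tuple(header["shape"])
    values = np.fromfile(path, dtype=np.float64).reshape(shape)
    grid = VoxelGrid(
        spacing=tuple(header["grid_spacing"]),
        counts=tuple(header["grid_counts"]),
        origin=tuple(header["grid_origin"]),
    )
    focal = FocalPlane(depth=header["dfp_cm"], index=header["focal_index"])
    return SystemMatrix(
        values=values, focal=focal, grid=grid, provenance=header["provenance"]
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def setup_from_config(cfg: dict | str | Path) -> ImagingSetup:
    """Build an :class:`ImagingSetup` from a YAML config (path or dict).

    Schema::

        optics: {mu_a: 0.02, mu_s_prime: 10.0, q: 1.0}
        slab:   {thickness: 3.0}
        grid:   {spacing: 0.1, extent: [3.0, 3.0, 3.0]}
        source: {entry_y: 1.5, entry_z: 1.5, strength: 1.0}
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    for section in ("optics", "slab", "grid", "source"):
        if section not in cfg:
            raise KeyError(f"config is missing the {section!r} section")
    o = cfg["optics"]
    optics = OpticalProperties(
        mu_a=float(o["mu_a"]), mu_s_prime=float(o["mu_s_prime"]), q=float(o.get("q", 1.0))
    )
    slab = SlabGeometry(thickness=float(cfg["slab"]["thickness"]))
    g = cfg["grid"]
    grid = VoxelGrid.from_extent(tuple(float(e) for e in g["extent"]), g["spacing"])
    s = cfg["source"]
    entry = (slab.source_plane, float(s["entry_y"]), float(s["entry_z"]))
    source = place_collimated_source(
        entry, optics, slab, strength=float(s.get("strength", 1.0))
    )
    return ImagingSetup(
        optics=optics,
        slab=slab,
        grid=grid,
        source=source,
        reference_pixel=int(cfg.get("reference_pixel", 0)),
    )
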