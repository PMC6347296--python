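"""Dwell-time matrices (DTMs) on cubic source-positioning grids.

Activity painting moves a point source through a regular 3-D grid inside
the scanner FOV, stopping at every grid point for a prescribed *dwell
time*.  Relative dwell times become relative activity concentrations in
the reconstructed image, so a DTM — one dwell value per grid point — fully
specifies a paintable activity distribution.

This module builds DTMs from analytic shape specifications (cube, sphere,
spherical shell, heart, gradient cube), extracts them from existing voxel
images through a dwell-to-concentration calibration line, and stores them
as NIfTI volumes with a JSON geometry sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .image import VoxelImage, _as_vec3

__all__ = [
    "GridGeometry",
    "DwellTimeMatrix",
    "ShapeSpec",
    "CalibrationLine",
    "make_shape_dtm",
    "make_gradient_cube_dtm",
    "dtm_from_image",
    "save_dtm",
    "load_dtm",
    "list_dtm_library",
]

_AXES = "xyz"


@dataclass
class GridGeometry:
    """Isotropic cubic grid of source stop positions.

    step_size : grid pitch in mm (the paper-style "step size", 4 mm default
    in most experiments); extent : bounding-box edge lengths in mm;
    origin : physical mm position of grid point (0,0,0) in the
    FOV-centred frame.  The number of points per axis is
    ``floor(extent/step) + 1``.
    """

    step_size: float
    extent: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.step_size = float(self.step_size)
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        self.extent = _as_vec3(self.extent, "extent")
        if np.any(self.extent < self.step_size):
            raise ValueError("extent must be >= step_size on every axis")
        self.origin = _as_vec3(self.origin, "origin")

    @classmethod
    def centered(cls, extent, step_size: float) -> "GridGeometry":
        """Grid of the given extent centred on the FOV origin."""
        extent = _as_vec3(extent, "extent")
        n = np.floor(extent / step_size).astype(int) + 1
        origin = -(n - 1) * step_size / 2.0
        return cls(step_size=step_size, extent=extent, origin=origin)

    @property
    def shape(self) -> tuple:
        return tuple(int(np.floor(e / self.step_size)) + 1 for e in self.extent)

    @property
    def center(self) -> np.ndarray:
        """Physical centre of the grid-point cloud (mm)."""
        return self.origin + (np.asarray(self.shape) - 1) * self.step_size / 2.0

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.step_size

    def point_coords(self) -> tuple:
        """Meshgrid of physical mm coordinates of all grid points."""
        return np.meshgrid(*(self.axis_coords(k) for k in range(3)), indexing="ij")

    def to_dict(self) -> dict:
        return {
            "step_size_mm": self.step_size,
            "extent_mm": self.extent.tolist(),
            "origin_mm": self.origin.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(step_size=d["step_size_mm"], extent=d["extent_mm"], origin=d["origin_mm"])


@dataclass
class DwellTimeMatrix:
    """Per-grid-point dwell times in seconds."""

    grid: GridGeometry
    dwell: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.dwell = np.asarray(self.dwell, dtype=float)
        if self.dwell.shape != self.grid.shape:
            raise ValueError(
                f"dwell shape {self.dwell.shape} does not match grid shape {self.grid.shape}"
            )
        if np.any(self.dwell < 0):
            raise ValueError("dwell times must be >= 0")
        if not np.any(self.dwell > 0):
            raise ValueError("DTM must contain at least one positive dwell")

    @property
    def total_dwell_s(self) -> float:
        return float(self.dwell.sum())

    def scaled(self, factor: float) -> "DwellTimeMatrix":
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return DwellTimeMatrix(grid=self.grid, dwell=self.dwell * factor, label=self.label)


@dataclass
class ShapeSpec:
    """Analytic shape with inside/outside dwell times.

    ``kind`` is one of cube, sphere, spherical_shell, heart, gradient_cube.
    Lengths are mm; ``center`` is an offset from the grid centre.  A grid
    point exactly on the surface counts as inside (inclusive comparisons).
    """

    kind: str
    dwell_in: float = 1.0
    dwell_out: float = 0.0
    edge: float | None = None
    radius: float | None = None
    inner_radius: float | None = None
    outer_radius: float | None = None
    size: float | None = None
    peak_dwell: float | None = None
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    _KINDS = ("cube", "sphere", "spherical_shell", "heart", "gradient_cube")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {self._KINDS}")
        if self.dwell_in < 0 or self.dwell_out < 0:
            raise ValueError("dwell times must be >= 0")
        self.center = _as_vec3(self.center, "center")
        for name in ("edge", "radius", "inner_radius", "outer_radius", "size", "peak_dwell"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kind == "cube" and self.edge is None:
            raise ValueError("cube requires edge")
        if self.kind == "sphere" and self.radius is None:
            raise ValueError("sphere requires radius")
        if self.kind == "spherical_shell":
            if self.inner_radius is None or self.outer_radius is None:
                raise ValueError("spherical_shell requires inner_radius and outer_radius")
            if self.inner_radius >= self.outer_radius:
                raise ValueError("inner_radius must be < outer_radius")
        if self.kind == "heart" and self.size is None:
            raise ValueError("heart requires size")
        if self.kind == "gradient_cube":
            if self.edge is None:
                raise ValueError("gradient_cube requires edge")
            if self.peak_dwell is None or self.peak_dwell <= 0:
                raise ValueError("gradient_cube requires peak_dwell > 0")

    # convenience constructors -------------------------------------------------
    @classmethod
    def cube(cls, edge, dwell_in=1.0, dwell_out=0.0, center=(0, 0, 0)):
        return cls("cube", edge=edge, dwell_in=dwell_in, dwell_out=dwell_out, center=center)

    @classmethod
    def sphere(cls, radius, dwell_in=1.0, dwell_out=0.0, center=(0, 0, 0)):
        return cls("sphere", radius=radius, dwell_in=dwell_in, dwell_out=dwell_out, center=center)

    @classmethod
    def spherical_shell(cls, inner_radius, outer_radius, dwell_in=1.0, dwell_out=0.0, center=(0, 0, 0)):
        return cls(
            "spherical_shell",
            inner_radius=inner_radius,
            outer_radius=outer_radius,
            dwell_in=dwell_in,
            dwell_out=dwell_out,
            center=center,
        )

    @classmethod
    def heart(cls, size, dwell_in=1.0, dwell_out=0.0, center=(0, 0, 0)):
        return cls("heart", size=size, dwell_in=dwell_in, dwell_out=dwell_out, center=center)

    @classmethod
    def gradient_cube(cls, edge, peak_dwell, center=(0, 0, 0)):
        return cls("gradient_cube", edge=edge, peak_dwell=peak_dwell, dwell_in=0.0, center=center)

    def half_extent(self) -> float:
        """Half-width of the shape's bounding cube (mm)."""
        if self.kind in ("cube", "gradient_cube"):
            return self.edge / 2.0
        if self.kind == "sphere":
            return self.radius
        if self.kind == "spherical_shell":
            return self.outer_radius
        return self.size / 2.0


@dataclass
class CalibrationLine:
    """Linear dwell-to-concentration map with zero intercept.

    ``concentration = (conc_max / dwell_max) * dwell``; the default values
    encode the observed 0–6 s dwell to 0–14 kBq/ml concentration span of a
    clinical scanner.
    """

    dwell_max: float = 6.0
    conc_max: float = 14.0

    def __post_init__(self):
        if self.dwell_max <= 0 or self.conc_max <= 0:
            raise ValueError("dwell_max and conc_max must be > 0")

    @property
    def slope(self) -> float:
        """kBq/ml per second of dwell."""
        return self.conc_max / self.dwell_max

    def dwell_to_conc(self, dwell):
        return np.asarray(dwell, dtype=float) * self.slope

    def conc_to_dwell(self, conc):
        return np.asarray(conc, dtype=float) / self.slope


def _check_fit(shape: ShapeSpec, grid: GridGeometry) -> np.ndarray:
    """Shape centre in physical mm; raises if the shape overflows the grid."""
    center = grid.center + shape.center
    half = shape.half_extent()
    lo = grid.origin
    hi = grid.origin + (np.asarray(grid.shape) - 1) * grid.step_size
    for k in range(3):
        if center[k] - half < lo[k] - 1e-9 or center[k] + half > hi[k] + 1e-9:
            raise ValueError(
                f"shape of half-extent {half:g} mm does not fit inside the grid "
                f"along axis {_AXES[k]} (grid spans [{lo[k]:g}, {hi[k]:g}] mm)"
            )
    return center


def _inside_mask(shape: ShapeSpec, grid: GridGeometry, center: np.ndarray) -> np.ndarray:
    x, y, z = grid.point_coords()
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    if shape.kind == "cube":
        h = shape.edge / 2.0
        return np.maximum.reduce([np.abs(dx), np.abs(dy), np.abs(dz)]) <= h + 1e-9
    if shape.kind == "sphere":
        return dx**2 + dy**2 + dz**2 <= shape.radius**2 + 1e-9
    if shape.kind == "spherical_shell":
        r2 = dx**2 + dy**2 + dz**2
        return (r2 >= shape.inner_radius**2 - 1e-9) & (r2 <= shape.outer_radius**2 + 1e-9)
    if shape.kind == "heart":
        # classic implicit heart surface; the surface reaches |z| ~ 1.3 in
        # normalized units, so scale by size/2.6 to keep it inside the
        # declared size-mm bounding cube; z is "up" (the lobes)
        s = shape.size / 2.6
        u, v, w = dx / s, dy / s, dz / s
        f = (u**2 + 2.25 * v**2 + w**2 - 1.0) ** 3 - u**2 * w**3 - (9.0 / 80.0) * v**2 * w**3
        return f <= 1e-9
    raise ValueError(f"no implicit surface for kind {shape.kind!r}")


def make_shape_dtm(shape: ShapeSpec, grid: GridGeometry) -> DwellTimeMatrix:
    """Rasterize a shape onto the grid: inside points get ``dwell_in``,
    outside points ``dwell_out``.  Gradient cubes are delegated to
    :func:`make_gradient_cube_dtm`."""
    center = _check_fit(shape, grid)
    if shape.kind == "gradient_cube":
        return make_gradient_cube_dtm(
            shape.edge, grid, shape.peak_dwell, center_offset=shape.center
        )
    inside = _inside_mask(shape, grid, center)
    dwell = np.where(inside, shape.dwell_in, shape.dwell_out)
    return DwellTimeMatrix(grid=grid, dwell=dwell, label=shape.kind)


def make_gradient_cube_dtm(
    edge: float,
    grid: GridGeometry,
    peak_dwell: float,
    center_offset=(0, 0, 0),
    metric: str = "chebyshev",
) -> DwellTimeMatrix:
    """Cube whose dwell rises linearly from 0 at the surface to
    ``peak_dwell`` at the centre.

    The default distance metric is Chebyshev (cube-shaped isolevels, the
    square ramp pattern); ``metric="euclidean"`` gives spherical isolevels
    clipped to the cube.
    """
    if peak_dwell <= 0:
        raise ValueError("peak_dwell must be > 0")
    spec = ShapeSpec.cube(edge, center=center_offset)
    center = _check_fit(spec, grid)
    x, y, z = grid.point_coords()
    dx, dy, dz = np.abs(x - center[0]), np.abs(y - center[1]), np.abs(z - center[2])
    if metric == "chebyshev":
        d = np.maximum.reduce([dx, dy, dz])
    elif metric == "euclidean":
        d = np.sqrt(dx**2 + dy**2 + dz**2)
    else:
        raise ValueError("metric must be 'chebyshev' or 'euclidean'")
    d_max = edge / 2.0
    dwell = peak_dwell * np.clip(1.0 - d / d_max, 0.0, None)
    inside_cube = np.maximum.reduce([dx, dy, dz]) <= d_max + 1e-9
    dwell = np.where(inside_cube, dwell, 0.0)
    return DwellTimeMatrix(grid=grid, dwell=dwell, label="gradient_cube")


def dtm_from_image(
    target: VoxelImage,
    grid: GridGeometry,
    cal: CalibrationLine,
    clip_above: bool = True,
) -> DwellTimeMatrix:
    """Extract a DTM from a target activity image.

    The target is sampled at the grid-point coordinates by trilinear
    interpolation and mapped through the inverse calibration line
    ``dwell = (dwell_max/conc_max) * concentration``.  Negative
    interpolated values clamp to zero; values above ``conc_max`` clamp to
    ``dwell_max`` when ``clip_above`` is set and extrapolate linearly
    otherwise.
    """
    if not np.any(target.values != 0):
        raise ValueError("empty target: image is all zero")
    x, y, z = grid.point_coords()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    idx = target.world_to_index(pts)
    lo_ok = np.all(idx >= -1e-6, axis=1)
    hi_ok = np.all(idx <= np.asarray(target.shape) - 1 + 1e-6, axis=1)
    if not np.all(lo_ok & hi_ok):
        bad = int(np.argmin(lo_ok & hi_ok))
        raise ValueError(
            f"grid point {pts[bad]} mm lies outside the target image extent"
        )
    conc = ndimage.map_coordinates(target.values, idx.T, order=1, mode="nearest")
    dwell = cal.conc_to_dwell(np.clip(conc, 0.0, None))
    if clip_above:
        dwell = np.minimum(dwell, cal.dwell_max)
    return DwellTimeMatrix(grid=grid, dwell=dwell.reshape(grid.shape), label="from_image")


# --------------------------------------------------------------------------
# DTM storage: NIfTI volume of dwell seconds + JSON geometry sidecar


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_dtm(dtm: DwellTimeMatrix, path) -> None:
    """Write dwell seconds as float32 NIfTI plus a JSON sidecar holding the
    grid geometry and label.  Round trip is lossless at float32."""
    path = Path(path)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = dtm.grid.step_size
    aff[:3, 3] = dtm.grid.origin
    nib.save(nib.Nifti1Image(dtm.dwell.astype(np.float32), aff), str(path))
    sidecar = dtm.grid.to_dict()
    sidecar["label"] = dtm.label
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_dtm(path) -> DwellTimeMatrix:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing DTM sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    grid = GridGeometry.from_dict(sidecar)
    dwell = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if dwell.shape != grid.shape:
        raise ValueError(
            f"DTM format error: array shape {dwell.shape} disagrees with "
            f"sidecar grid shape {grid.shape}"
        )
    if np.any(dwell < 0):
        raise ValueError("DTM format error: negative dwell values on read")
    return DwellTimeMatrix(grid=grid, dwell=dwell, label=sidecar.get("label", ""))


def list_dtm_library(directory) -> list:
    """Sorted labels of every DTM stored in a directory."""
    directory = Path(directory)
    labels = []
    for nii in list(directory.glob("*.nii")) + list(directory.glob("*.nii.gz")):
        sidecar = _sidecar_path(nii)
        if sidecar.exists():
            labels.append(json.loads(sidecar.read_text()).get("label", nii.name))
    return sorted(labels)
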