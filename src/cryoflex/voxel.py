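"""Voxel grids: the common container for densities, probabilities and RMSF.

A :class:`VoxelGrid` is a 3D scalar field on an isotropic lattice with a
physical voxel size (Å) and a world-frame origin.  The origin is the world
coordinate of the *center* of voxel ``(0, 0, 0)``; indices are 0-based and
the array is always in (x, y, z) axis order, whatever order the file on disk
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "read_density_map",
    "write_density_map",
    "resample_to_voxel_size",
    "world_to_voxel",
    "voxel_center",
    "OUT_OF_BOUNDS",
]

#: Sentinel returned by :func:`world_to_voxel` for coordinates outside the grid.
OUT_OF_BOUNDS = None


@dataclass
class VoxelGrid:
    """3D scalar field with physical scale and placement.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field; density in map units, probability in [0, 1] or RMSF in Å.
    voxel_size : float
        Edge length of a voxel in Å (isotropic).
    origin : ndarray, shape (3,)
        World coordinate (Å) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with all dims >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.voxel_size, self.origin.copy())

    def same_frame(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        """True if shape, voxel size and origin agree within ``atol``."""
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= atol
            and bool(np.all(np.abs(self.origin - other.origin) <= atol))
        )


def read_density_map(path) -> VoxelGrid:
    """Read an MRC2014/CCP4 volume, normalizing axis order to (x, y, z).

    The axis-correspondence header fields (MAPC/MAPR/MAPS) are honored and the
    data rearranged to ascending x, y, z.  The origin is taken from the ORIGIN
    header record if any component is nonzero, otherwise from the start
    indices scaled by the voxel size.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, SystemError, ValueError) as exc:
        raise OSError(f"cannot read map {path!r}: {exc}") from exc
    # start indices are stored in file (column, row, section) order; map them
    # to x,y,z through the axis-correspondence words before reordering.
    axis_corr = [m.header_i32(w) for w in (17, 18, 19)]  # MAPC, MAPR, MAPS
    if sorted(axis_corr) != [1, 2, 3]:
        raise ValueError(f"invalid axis correspondence {axis_corr} in {path!r}")
    start_crs = [m.header_i32(w) for w in (5, 6, 7)]
    start_xyz = [0, 0, 0]
    for file_axis, xyz_axis in enumerate(axis_corr):
        start_xyz[xyz_axis - 1] = start_crs[file_axis]
    # voxel size from the cell dimensions and sampling counts (words 8-13),
    # which are stored in crystal x,y,z order already
    sampling = np.array([m.header_i32(w) for w in (8, 9, 10)], dtype=np.int64)
    cell = np.array([m.header_float(w) for w in (11, 12, 13)])
    if np.any(sampling <= 0) or np.any(cell <= 0):
        raise ValueError(f"inconsistent sampling/cell header in {path!r}")
    spacing = cell / sampling
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True)
    voxel_size = float(spacing[0])
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=np.float64)
    if np.all(origin == 0.0):
        origin = np.asarray(start_xyz, dtype=np.float64) * spacing
    return VoxelGrid(values, voxel_size, origin)


def write_density_map(grid: VoxelGrid, path) -> None:
    """Write ``grid`` as an MRC2014 (mode 2, float32) volume."""
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.shape
    vs = grid.voxel_size
    g.set_unit_cell(gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(val))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, SystemError) as exc:
        raise OSError(f"cannot write map {path!r}: {exc}") from exc


def resample_to_voxel_size(grid: VoxelGrid, target: float = 1.5) -> VoxelGrid:
    """Resample to an isotropic ``target`` voxel size (Å) by cubic spline.

    Output shape is ``round(shape * original / target)`` per axis; edge values
    are extended outside the grid; the world origin is preserved.  A grid
    already at the target size is returned unchanged (copy).
    """
    if not target > 0:
        raise ValueError("target voxel size must be positive")
    zoom = grid.voxel_size / target
    if abs(zoom - 1.0) < 1e-9:
        return grid.copy()
    values = ndimage.zoom(grid.values, zoom, order=3, mode="nearest", grid_mode=False)
    return VoxelGrid(np.ascontiguousarray(values, np.float32), target, grid.origin.copy())


def world_to_voxel(grid: VoxelGrid, coord) -> tuple[int, int, int] | None:
    """Index of the voxel whose center is nearest to the world coordinate.

    Returns :data:`OUT_OF_BOUNDS` (``None``) when the nearest voxel falls
    outside the grid; out-of-bounds is a value, not an error.
    """
    coord = np.asarray(coord, dtype=np.float64)
    idx = np.floor((coord - grid.origin) / grid.voxel_size + 0.5).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        return OUT_OF_BOUNDS
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def voxel_center(grid: VoxelGrid, index) -> np.ndarray:
    """World coordinate (Å) of the center of voxel ``index``."""
    return grid.origin + np.asarray(index, dtype=np.float64) * grid.voxel_size
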