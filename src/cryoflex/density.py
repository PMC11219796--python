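"""Simulated density maps from atomic models, and map-model comparison.

Each atom is rendered as an isotropic 3D Gaussian centered on its position,
with standard deviation 0.225 x nominal resolution (the molmap-style
convention) and integral equal to the atomic mass; contributions are summed
on the target grid and truncated beyond 4 standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AtomicModel
from .voxel import VoxelGrid, world_to_voxel

__all__ = [
    "SimulatedMapStats",
    "SIGMA_PER_RESOLUTION",
    "simulate_density",
    "binarize_simulated_map",
    "one_hot_encode",
    "one_hot_decode",
    "occupancy_annotation",
    "map_model_fitness",
]

#: Gaussian width as a fraction of nominal resolution (molmap convention).
SIGMA_PER_RESOLUTION = 0.225

#: Truncation radius in Gaussian standard deviations.
TRUNCATION_SIGMAS = 4.0


@dataclass
class SimulatedMapStats:
    """Density statistics of a simulated map used for binarization."""

    sigma: float  # standard deviation of density values about their mean

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def threshold(self) -> float:
        return 3.0 * self.sigma


def simulate_density(model: AtomicModel, grid: VoxelGrid,
                     resolution: float = 5.0) -> VoxelGrid:
    """Render ``model`` as a density map on the frame of ``grid``.

    Returns a new grid (same shape/voxel size/origin as ``grid``) whose
    values are the summed atomic Gaussians; atoms outside the truncation
    radius of every voxel contribute nothing, and a grid with no atoms in
    range is all zeros.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    sigma = SIGMA_PER_RESOLUTION * resolution
    cutoff = TRUNCATION_SIGMAS * sigma
    vs = grid.voxel_size
    shape = np.asarray(grid.shape)
    out = np.zeros(grid.shape, dtype=np.float64)
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
    r_vox = int(np.ceil(cutoff / vs))
    for mass, xyz in zip(model.masses, model.coords):
        center = (xyz - grid.origin) / vs  # fractional voxel coordinate
        lo = np.maximum(np.ceil(center - r_vox).astype(int), 0)
        hi = np.minimum(np.floor(center + r_vox).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        ax = [(np.arange(lo[d], hi[d] + 1) - center[d]) * vs for d in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        blob = np.where(r2 <= cutoff * cutoff,
                        mass * norm * np.exp(-0.5 * r2 / sigma ** 2), 0.0)
        out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += blob
    return VoxelGrid(out.astype(np.float32), vs, grid.origin.copy())


def binarize_simulated_map(grid: VoxelGrid,
                           multiplier: float = 3.0) -> tuple[VoxelGrid, SimulatedMapStats]:
    """Threshold a simulated map at ``multiplier`` x sigma of its densities.

    sigma is the standard deviation of all density values about their mean;
    voxels with density strictly above the threshold are encoded 1, else 0.
    An all-constant map (sigma = 0) yields an all-zero binary map.
    """
    sigma = float(np.std(grid.values))
    stats = SimulatedMapStats(sigma)
    if sigma == 0.0:
        binary = np.zeros(grid.shape, dtype=np.float32)
    else:
        binary = (grid.values > multiplier * sigma).astype(np.float32)
    return VoxelGrid(binary, grid.voxel_size, grid.origin.copy()), stats


def one_hot_encode(binary: VoxelGrid) -> np.ndarray:
    """Binary grid -> 2-channel one-hot array (2, nx, ny, nz).

    Channel 0 marks unoccupied voxels (1 - b), channel 1 occupied (b);
    channels sum to 1 everywhere.
    """
    b = binary.values
    if not np.all((b == 0) | (b == 1)):
        raise ValueError("one_hot_encode requires a binary grid")
    return np.stack([1.0 - b, b]).astype(np.float32)


def one_hot_decode(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`one_hot_encode` (returns the binary field)."""
    return np.asarray(channels)[1]


def occupancy_annotation(model: AtomicModel, grid: VoxelGrid) -> VoxelGrid:
    """Binary grid marking voxels whose center is nearest to >= 1 heavy atom."""
    occ = np.zeros(grid.shape, dtype=np.float32)
    for xyz in model.coords:
        idx = world_to_voxel(grid, xyz)
        if idx is not None:
            occ[idx] = 1.0
    return VoxelGrid(occ, grid.voxel_size, grid.origin.copy())


def map_model_fitness(simulated: VoxelGrid, experimental: VoxelGrid) -> float:
    """Pearson correlation between two maps over all voxels of the common grid.

    Used to screen how well an atomic model explains an experimental map
    (a fitness above 0.7 marks a well-fitted pair).
    """
    if simulated.shape != experimental.shape:
        raise ValueError("maps must share a shape")
    if abs(simulated.voxel_size - experimental.voxel_size) > 1e-6:
        raise ValueError("maps must share a voxel size")
    a = simulated.values.ravel().astype(np.float64)
    b = experimental.values.ravel().astype(np.float64)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance map")
    return float(np.corrcoef(a, b)[0, 1])
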