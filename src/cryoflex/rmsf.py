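"""Ground-truth RMSF from conformational ensembles.

RMSF_i = sqrt( mean_t || x_i(t) - x̃_i ||^2 ), the time-averaged deviation of
atom i from its mean position x̃_i after removing global translation and
rotation.  Frames are first aligned to the initial conformation, then to an
iteratively refined heavy-atom mean structure (two refinement passes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import AtomicModel, ConformationEnsemble
from .voxel import VoxelGrid, world_to_voxel

__all__ = [
    "RMSFProfile",
    "RMSFMap",
    "kabsch_superpose",
    "ensemble_rmsf",
    "rmsf_to_voxels",
    "aggregate_to_residues",
    "normalize_rmsf",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Point sets too small or degenerate for superposition."""


@dataclass
class RMSFProfile:
    """Per-atom RMSF in Å, aligned with an AtomicModel's atom order."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("profile must be a 1D array with >= 1 value")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("RMSF values must be finite and non-negative")

    def __len__(self):
        return len(self.values)


@dataclass
class RMSFMap:
    """Voxelized RMSF plus the boolean mask of labeled (atom-occupied) voxels."""

    values: VoxelGrid
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must share a shape")
        if not np.all(np.isfinite(self.values.values[self.mask])):
            raise ValueError("labeled voxels must be finite")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference`` over all rigid
    transforms.  Raises :class:`DegenerateInputError` for < 3 points or
    (near-)collinear point sets, where the rotation is not determined.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError("need at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    scale = max(s[0], 1e-300)
    if s[1] / scale < 1e-9:
        raise DegenerateInputError("collinear point set: rotation undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = rc - rot @ mc
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, t, rmsd


def _align_frames(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        rot, t, _ = kabsch_superpose(frames[f], reference)
        out[f] = frames[f] @ rot.T + t
    return out


def ensemble_rmsf(ensemble: ConformationEnsemble,
                  n_refine: int = 2) -> RMSFProfile:
    """Per-atom RMSF of an ensemble after rigid-body alignment.

    Procedure: align every frame to the first, compute the heavy-atom mean
    structure, then realign to the mean and recompute it (``n_refine``
    passes); RMSF is the root-mean-square deviation from the final mean.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    frames = _align_frames(ensemble.frames, ensemble.frames[0])
    for _ in range(n_refine):
        mean = frames.mean(axis=0)
        frames = _align_frames(frames, mean)
    mean = frames.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))
    return RMSFProfile(rmsf)


def rmsf_to_voxels(profile: RMSFProfile, model: AtomicModel,
                   grid: VoxelGrid) -> RMSFMap:
    """Deposit per-atom RMSF onto nearest voxels (collisions -> mean)."""
    if len(profile) != model.n_atoms:
        raise ValueError("profile length must match the atom count")
    sums = np.zeros(grid.shape, dtype=np.float64)
    counts = np.zeros(grid.shape, dtype=np.int64)
    for value, xyz in zip(profile.values, model.coords):
        idx = world_to_voxel(grid, xyz)
        if idx is None:
            continue
        sums[idx] += value
        counts[idx] += 1
    mask = counts > 0
    if not mask.any():
        warnings.warn("no atom fell inside the grid; RMSF map is empty")
    values = np.zeros(grid.shape, dtype=np.float32)
    values[mask] = (sums[mask] / counts[mask]).astype(np.float32)
    return RMSFMap(VoxelGrid(values, grid.voxel_size, grid.origin.copy()), mask)


def aggregate_to_residues(atom_values, model: AtomicModel
                          ) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Average per-atom values over residues.

    Returns ``(keys, values)`` where ``keys`` are distinct (chain, residue
    index) pairs in order of first appearance and ``values[i]`` is the mean
    of that residue's atom values.
    """
    atom_values = np.asarray(atom_values, dtype=np.float64)
    if len(atom_values) != model.n_atoms:
        raise ValueError("one value per atom required")
    keys = model.residue_keys()
    pos = {k: i for i, k in enumerate(keys)}
    sums = np.zeros(len(keys))
    counts = np.zeros(len(keys))
    for v, ch, ri in zip(atom_values, model.chain_ids, model.residue_index):
        i = pos[(ch, int(ri))]
        sums[i] += v
        counts[i] += 1
    return keys, sums / counts


def normalize_rmsf(values) -> np.ndarray:
    """Z-score values with the population standard deviation.

    A constant vector returns all zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("need at least one value")
    std = values.std()  # population std
    if std == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / std
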