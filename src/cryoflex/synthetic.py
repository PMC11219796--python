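"""Synthetic pseudo-proteins, fluctuation ensembles and blurred noisy maps.

Stands in for an experimentally derived training corpus: a pseudo-protein is
a self-avoiding chain of carbon-like pseudo-residues; its ensemble fluctuates
with per-atom isotropic Gaussian amplitudes that grow from the core to the
periphery (the pattern real proteins show); the "experimental" map is the
frame-averaged simulated density plus white noise, so flexible regions are
genuinely blurred — the physical signal that links map intensity to
flexibility.  True per-atom RMSF is known in closed form: for per-axis
amplitude sigma_i the expected RMSF is sigma_i * sqrt(3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .density import simulate_density
from .rmsf import RMSFMap, RMSFProfile, aggregate_to_residues, ensemble_rmsf, rmsf_to_voxels
from .structure import (AtomicModel, ConformationEnsemble, write_atomic_model,
                        write_ensemble)
from .voxel import VoxelGrid, write_density_map

__all__ = ["SyntheticSpec", "SyntheticEntry", "GenerationError",
           "generate_pseudo_protein", "generate_ensemble",
           "generate_heterogeneous_map", "make_dataset", "make_entry"]

CARBON_MASS = 12.011


class GenerationError(RuntimeError):
    """Self-avoiding walk failed within the retry budget."""


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic study entry.

    ``bond_length`` is the fixed step between consecutive pseudo-residues
    (3.8 Å, the Cα-Cα virtual bond); ``min_distance`` the self-avoidance
    limit; fluctuation amplitudes ramp linearly from ``sigma_min`` at the
    centroid to ``sigma_max`` at the periphery (Å per axis); ``noise_level``
    is the white-noise standard deviation as a fraction of the noise-free
    map maximum.  ``confinement_radius`` (Å) keeps the walk globular; by
    default 3.0 * n_atoms^(1/3), which reproduces protein-like packing.
    """

    n_atoms: int = 300
    bond_length: float = 3.8
    min_distance: float = 3.0
    sigma_min: float = 0.3
    sigma_max: float = 1.5
    n_frames: int = 300
    resolution: float = 5.0
    noise_level: float = 0.05
    voxel_size: float = 1.5
    margin_voxels: int = 10
    confinement_radius: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")

    @property
    def radius(self) -> float:
        if self.confinement_radius is not None:
            return self.confinement_radius
        return 3.0 * self.n_atoms ** (1.0 / 3.0)


@dataclass
class SyntheticEntry:
    """One complete study entry: map, model and known ground truth."""

    name: str
    cryo_map: VoxelGrid
    model: AtomicModel
    ensemble: ConformationEnsemble
    sigma: np.ndarray                      # true per-axis amplitudes (Å)
    profile: RMSFProfile                   # ensemble-derived per-atom RMSF
    truth_map: RMSFMap
    residue_keys: list = field(default_factory=list)
    residue_truth: np.ndarray | None = None
    seed: int = 0


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_pseudo_protein(spec: SyntheticSpec,
                            rng: np.random.Generator | None = None) -> AtomicModel:
    """Self-avoiding random walk with fixed 3.8 Å steps, one chain.

    One pseudo-residue per atom; reproducible given the spec seed.  Raises
    :class:`GenerationError` if self-avoidance cannot be satisfied within a
    bounded number of restarts.
    """
    if spec.n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    for _ in range(50):  # walk restarts
        coords = [np.zeros(3)]
        failed = False
        for _i in range(1, spec.n_atoms):
            for _try in range(200):
                cand = coords[-1] + spec.bond_length * _random_unit(rng)
                if np.linalg.norm(cand) > spec.radius:
                    continue
                if len(coords) > 1:
                    d = np.linalg.norm(np.asarray(coords[:-1]) - cand, axis=1)
                    if d.min() < spec.min_distance:
                        continue
                coords.append(cand)
                break
            else:
                failed = True
                break
        if not failed:
            n = spec.n_atoms
            return AtomicModel(["C"] * n, np.full(n, CARBON_MASS),
                               np.asarray(coords), np.arange(1, n + 1),
                               ["A"] * n, ["CA"] * n, ["ALA"] * n)
    raise GenerationError("self-avoiding walk failed after bounded retries")


def generate_ensemble(model: AtomicModel, spec: SyntheticSpec,
                      rng: np.random.Generator | None = None
                      ) -> tuple[ConformationEnsemble, np.ndarray]:
    """Fluctuation ensemble with known per-atom amplitudes.

    sigma_i ramps linearly with the atom's distance from the structure
    centroid (periphery more flexible); frames are the mean structure plus
    i.i.d. isotropic Gaussian displacements of per-axis std sigma_i, so the
    expected RMSF is sigma_i * sqrt(3).
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    d = np.linalg.norm(model.coords - model.coords.mean(axis=0), axis=1)
    dmax = d.max() if d.max() > 0 else 1.0
    sigma = spec.sigma_min + (spec.sigma_max - spec.sigma_min) * d / dmax
    noise = rng.normal(size=(spec.n_frames, model.n_atoms, 3))
    frames = model.coords[None] + sigma[None, :, None] * noise
    return ConformationEnsemble(frames, model), sigma


def generate_heterogeneous_map(ensemble: ConformationEnsemble,
                               spec: SyntheticSpec,
                               rng: np.random.Generator | None = None
                               ) -> VoxelGrid:
    """Frame-averaged simulated density plus white noise.

    Averaging the per-frame densities blurs flexible regions exactly as a
    reconstruction from many instantaneous conformations would; the grid
    encloses every frame with a margin.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    vs = spec.voxel_size
    lo = ensemble.frames.reshape(-1, 3).min(axis=0) - spec.margin_voxels * vs
    hi = ensemble.frames.reshape(-1, 3).max(axis=0) + spec.margin_voxels * vs
    shape = np.ceil((hi - lo) / vs).astype(int) + 1
    base = VoxelGrid(np.zeros(shape, np.float32), vs, lo)
    total = np.zeros(shape, dtype=np.float64)
    mdl = ensemble.model
    for f in range(ensemble.n_frames):
        frame_model = AtomicModel(mdl.elements, mdl.masses, ensemble.frames[f],
                                  mdl.residue_index, mdl.chain_ids,
                                  mdl.atom_names, mdl.residue_names)
        total += simulate_density(frame_model, base, spec.resolution).values
    total /= ensemble.n_frames
    if spec.noise_level > 0 and total.max() > 0:
        total = total + rng.normal(0.0, spec.noise_level * total.max(), shape)
    return VoxelGrid(total.astype(np.float32), vs, lo)


def make_entry(spec: SyntheticSpec, name: str | None = None) -> SyntheticEntry:
    """Generate one complete entry from a spec (all randomness from its seed)."""
    rng = np.random.default_rng(spec.seed)
    model = generate_pseudo_protein(spec, rng)
    ensemble, sigma = generate_ensemble(model, spec, rng)
    cryo = generate_heterogeneous_map(ensemble, spec, rng)
    profile = ensemble_rmsf(ensemble)
    truth = rmsf_to_voxels(profile, model, cryo)
    keys, res_truth = aggregate_to_residues(profile.values, model)
    return SyntheticEntry(name or f"entry{spec.seed}", cryo, model, ensemble,
                          sigma, profile, truth, keys, res_truth, spec.seed)


def make_dataset(n_entries: int, spec: SyntheticSpec = SyntheticSpec(),
                 seed: int = 0, out_dir=None) -> list[SyntheticEntry]:
    """Generate ``n_entries`` entries with per-entry seeds derived from ``seed``.

    When ``out_dir`` is given, each entry is written to disk (MRC map, PDB
    model, multi-model PDB ensemble, RMSF tables) along with a manifest of
    specs/seeds from which any entry can be regenerated bit-identically.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_entries)
    entries = []
    manifest = []
    for i, s in enumerate(child_seeds):
        espec = SyntheticSpec(**{**asdict(spec), "seed": int(s % (2 ** 31))})
        entry = make_entry(espec, name=f"entry{i:03d}")
        entries.append(entry)
        manifest.append({"name": entry.name, "spec": asdict(espec)})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for entry in entries:
            base = out / entry.name
            write_density_map(entry.cryo_map, f"{base}_map.mrc")
            write_atomic_model(entry.model, f"{base}_model.pdb",
                               bfactors=entry.profile.values)
            write_ensemble(entry.ensemble, f"{base}_ensemble.pdb")
            np.savetxt(f"{base}_rmsf.txt",
                       np.column_stack([np.arange(1, entry.model.n_atoms + 1),
                                        entry.profile.values]),
                       header="atom_index rmsf_A", fmt=("%d", "%.6f"))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return entries
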