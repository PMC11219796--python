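"""Atomic models and conformational ensembles.

Models are read from PDB/mmCIF with gemmi; only heavy atoms of polymer
residues are kept (hydrogens, waters and hetero small molecules are dropped),
matching the convention that flexibility labels and simulated densities are
computed from heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomicModel",
    "ConformationEnsemble",
    "read_atomic_model",
    "read_ensemble",
    "write_atomic_model",
    "write_ensemble",
    "EmptyModelError",
]


class EmptyModelError(ValueError):
    """No heavy atoms left after filtering."""


@dataclass
class AtomicModel:
    """Ordered heavy atoms with element, mass, position and residue identity.

    Arrays are index-aligned: atom ``i`` has element ``elements[i]``, mass
    ``masses[i]`` (Da), world coordinate ``coords[i]`` (Å), and belongs to
    residue ``residue_index[i]`` of chain ``chain_ids[i]``.
    """

    elements: list[str]
    masses: np.ndarray
    coords: np.ndarray
    residue_index: np.ndarray
    chain_ids: list[str]
    atom_names: list[str] | None = None
    residue_names: list[str] | None = None

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        n = len(self.elements)
        if n < 1:
            raise EmptyModelError("model must contain at least one atom")
        if not (len(self.masses) == len(self.coords)
                == len(self.residue_index) == len(self.chain_ids) == n):
            raise ValueError("atom attribute arrays must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.atom_names is None:
            self.atom_names = list(self.elements)
        if self.residue_names is None:
            self.residue_names = ["ALA"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Distinct (chain, residue index) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for ch, ri in zip(self.chain_ids, self.residue_index):
            seen.setdefault((ch, int(ri)), None)
        return list(seen)

    def translated(self, shift) -> "AtomicModel":
        return AtomicModel(self.elements, self.masses,
                           self.coords + np.asarray(shift, float),
                           self.residue_index, self.chain_ids,
                           self.atom_names, self.residue_names)


@dataclass
class ConformationEnsemble:
    """F frames of identical atom topology; the source of ground-truth RMSF."""

    frames: np.ndarray  # (F, N, 3) Å
    model: AtomicModel | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _structure_to_model(st: gemmi.Structure, model_index: int = 0) -> AtomicModel:
    st.setup_entities()
    mdl = st[model_index]
    elements, masses, coords, resi, chains, names, resnames = [], [], [], [], [], [], []
    for chain in mdl:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_polymer = bool(info and (info.is_amino_acid() or info.is_nucleic_acid()))
            if res.het_flag == "H" and not is_polymer:
                continue  # hetero small molecule / ligand
            for atom in res:
                if atom.is_hydrogen():
                    continue
                elements.append(atom.element.name)
                masses.append(atom.element.weight)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                resi.append(res.seqid.num)
                chains.append(chain.name)
                names.append(atom.name)
                resnames.append(res.name)
    if not elements:
        raise EmptyModelError("no heavy polymer atoms found")
    return AtomicModel(elements, masses, coords, resi, chains, names, resnames)


def read_atomic_model(path) -> AtomicModel:
    """Read heavy atoms of the first model in a PDB or mmCIF file."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, SystemError, ValueError) as exc:
        raise OSError(f"cannot parse structure {path!r}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"no models in {path!r}")
    return _structure_to_model(st, 0)


def read_ensemble(path) -> ConformationEnsemble:
    """Read a multi-model PDB as a conformational ensemble.

    All models must share the atom topology of the first.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, SystemError, ValueError) as exc:
        raise OSError(f"cannot parse structure {path!r}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"no models in {path!r}")
    ref = _structure_to_model(st, 0)
    frames = np.empty((len(st), ref.n_atoms, 3))
    for i in range(len(st)):
        m = _structure_to_model(st, i)
        if m.n_atoms != ref.n_atoms:
            raise ValueError(f"model {i} has {m.n_atoms} atoms, expected {ref.n_atoms}")
        frames[i] = m.coords
    return ConformationEnsemble(frames, ref)


def _build_structure(model: AtomicModel, frames: np.ndarray,
                     bfactors: np.ndarray | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "cryoflex"
    for fi, coords in enumerate(frames):
        mdl = gemmi.Model(fi + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple[str, int], gemmi.Residue] = {}
        for i in range(model.n_atoms):
            ch_name = model.chain_ids[i]
            if ch_name not in chain_map:
                chain = gemmi.Chain(ch_name)
                mdl.add_chain(chain)
                chain_map[ch_name] = mdl[len(mdl) - 1]
            key = (ch_name, int(model.residue_index[i]))
            if key not in res_map:
                res = gemmi.Residue()
                res.name = model.residue_names[i]
                res.seqid = gemmi.SeqId(int(model.residue_index[i]), " ")
                chain_map[ch_name].add_residue(res)
                ch = chain_map[ch_name]
                res_map[key] = ch[len(ch) - 1]
            atom = gemmi.Atom()
            atom.name = model.atom_names[i]
            atom.element = gemmi.Element(model.elements[i])
            atom.pos = gemmi.Position(*coords[i])
            atom.occ = 1.0
            atom.b_iso = float(bfactors[i]) if bfactors is not None else 0.0
            res_map[key].add_atom(atom)
        st.add_model(mdl)
    st.setup_entities()
    return st


def write_atomic_model(model: AtomicModel, path,
                       bfactors: np.ndarray | None = None) -> None:
    """Write a model as PDB; ``bfactors`` fills the B-factor column (e.g. RMSF)."""
    st = _build_structure(model, model.coords[None], bfactors)
    st.write_pdb(str(path))


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB."""
    if ensemble.model is None:
        raise ValueError("ensemble carries no atom topology")
    st = _build_structure(ensemble.model, ensemble.frames)
    st.write_pdb(str(path))
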