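"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import cryoflex as cf


@pytest.fixture
def rng():
    # function-scoped: every test sees the same fresh stream, independent of
    # execution order
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """A small but complete synthetic study entry specification."""
    return cf.SyntheticSpec(n_atoms=60, n_frames=60, seed=7)


@pytest.fixture(scope="session")
def small_entry(small_spec):
    return cf.make_entry(small_spec)


@pytest.fixture
def random_grid(rng):
    values = rng.normal(size=(12, 10, 14)).astype(np.float32)
    return cf.VoxelGrid(values, 1.5, np.array([3.0, -4.5, 0.0]))


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  H   ALA A   1       0.500   0.800   0.300  1.00  0.00           H
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.696   0.000  1.00  0.00           C
ATOM      8  N   SER A   3       6.139   3.864   0.000  1.00  0.00           N
ATOM      9  CA  SER A   3       7.590   3.919   0.000  1.00  0.00           C
ATOM     10  OG  SER A   3       8.103   5.247   0.000  1.00  0.00           O
HETATM   11  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
HETATM   12  C1  LIG A 201      12.000  12.000  12.000  1.00  0.00           C
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three_res.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path
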