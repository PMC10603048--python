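"""Shared fixtures: toy structures, complexes and trajectories.

Everything is generated programmatically with fixed seeds; no fixture
files are read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
import biotite.structure as struc

from ppstab.io import ComplexDefinition, Selection, Structure
from ppstab import synthetic as syn

_ELEMENT_GUESS = {
    "N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "NZ": "N",
    "OE1": "O", "OE2": "O", "OD1": "O", "OD2": "O", "NH1": "N",
    "NH2": "N", "NE": "N", "CG": "C", "CD": "C", "CE": "C",
}


def make_structure(residues, hetero=False) -> Structure:
    """Build a Structure from [(chain, res_id, res_name, {atom: xyz})] specs."""
    records = []
    for chain, res_id, res_name, atoms in residues:
        for name, xyz in atoms.items():
            records.append((chain, res_id, res_name, name, xyz))
    arr = struc.AtomArray(len(records))
    arr.chain_id = np.array([r[0] for r in records], dtype="U4")
    arr.res_id = np.array([r[1] for r in records], dtype=int)
    arr.ins_code = np.array([""] * len(records), dtype="U1")
    arr.res_name = np.array([r[2] for r in records], dtype="U5")
    arr.atom_name = np.array([r[3] for r in records], dtype="U6")
    arr.hetero = np.full(len(records), hetero, dtype=bool)
    arr.element = np.array(
        [_ELEMENT_GUESS.get(r[3], r[3][:1]) for r in records], dtype="U2"
    )
    arr.coord = np.array([r[4] for r in records], dtype=np.float32)
    return Structure(arr)


def translated_copy_complex(sequence="AEALKKALDEAL", offset=8.0):
    """Receptor plus a partner that is the same chain translated along +x.

    Diagonal Calpha pairs are exactly parallel to the x axis, which makes
    drift-induced separation changes exact.
    """
    rec = syn.build_toy_peptide(sequence, "helical", "A")
    par_atoms = rec.atoms.copy()
    par_atoms.chain_id = np.array(["B"] * par_atoms.array_length(), dtype="U4")
    par_atoms.coord = par_atoms.coord + np.array([offset, 0, 0], dtype=np.float32)
    cplx = Structure(rec.atoms + par_atoms)
    cdef = ComplexDefinition(Selection("A"), (Selection("B"),), "translated copy")
    return cplx, cdef


@pytest.fixture(scope="session")
def toy_peptide() -> Structure:
    return syn.build_toy_peptide("AEALKKALDEAL", "helical", "A")


@pytest.fixture(scope="session")
def toy_complex():
    rec = syn.build_toy_peptide("AEALKKALDEALKKALEALKKALG", "helical", "A")
    par = syn.build_toy_peptide("AEKLAELKAL", "extended", "B")
    return syn.make_complex(rec, par, gap=4.0)


@pytest.fixture(scope="session")
def bound_trajectory(toy_complex):
    cplx, cdef = toy_complex
    return syn.trajectory_bound(cplx, sigma=0.1, n_frames=50, seed=11), cdef


@pytest.fixture(scope="session")
def dissociating_trajectory(toy_complex):
    cplx, cdef = toy_complex
    return (
        syn.trajectory_dissociating(
            cplx, cdef, drift=[0.05, 0.0, 0.0], sigma=0.0, n_frames=100, seed=12
        ),
        cdef,
    )
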